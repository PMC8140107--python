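"""Epidemic spreading model (ESM) on a brain connectome.

Each gray-matter region ``i`` carries an agent level ``S_i(t)`` (e.g.
misfolded-protein burden, raw signal or probability).  Regional dynamics
follow a logistic-style balance between infection-like accumulation and
clearance::

    dS_i/dt = (1 - S_i/maxS) * eps_i(t) - delta_i(t) * S_i

where the incoming pressure ``eps_i`` mixes extrinsic spreading from
connected regions with intrinsic within-region propagation::

    eps_i = sum_{j != i} Pa[j->i] * beta_j^ext * S_j + Pa[i->i] * beta_i^int * S_i
    beta_i^ext = g(t) * beta_i,   beta_i^int = (1 - g(t)) * beta_i

and ``g(t)`` is the Gini coefficient of the instantaneous regional agent
distribution: equality across regions (g = 0) keeps propagation local,
strong inequality (g -> 1) pushes it through the connectome.  Production and
clearance rates are either constant (``beta_o``, ``delta_o``) or saturating
functions of the local agent level (sigmoid mode)::

    beta_i  = 1 - exp(-beta_o  * S_i / maxS)
    delta_i =     exp(-delta_o * S_i / maxS)

Fitting minimizes the squared misfit over all regions and time points by
multistart bounded least squares, with epicenter identification via
backward integration to the (possibly estimated) onset time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares
from scipy.stats import qmc

from .io import Connectome, RegionalSeries

__all__ = [
    "ESMParams",
    "ESMState",
    "ESMFit",
    "gini_coefficient",
    "regional_rates",
    "esm_simulate",
    "esm_fit",
    "effective_rates",
]


@dataclass
class ESMParams:
    """Parameter set of the spreading model.

    ``S0`` holds the agent levels at the onset time ``t0``; entries outside
    ``epicenters`` must stay at or below ``nonepicenter_ceiling`` — regions
    below that ceiling are considered agent-free up to background noise.
    """

    beta_o: float
    delta_o: float
    S0: np.ndarray
    rate_mode: str = "sigmoid"
    onset_time: float = 0.0
    maxS: float = 1.0
    epicenters: list[int] = field(default_factory=list)
    nonepicenter_ceiling: float = 0.05
    max_epicenters: int = 4

    def __post_init__(self) -> None:
        if self.rate_mode not in ("sigmoid", "constant"):
            raise ValueError(f"unknown rate_mode {self.rate_mode!r}")
        if self.beta_o < 0 or self.delta_o < 0:
            raise ValueError("beta_o and delta_o must be nonnegative")
        if self.maxS <= 0:
            raise ValueError("maxS must be positive")
        self.S0 = np.asarray(self.S0, dtype=float)
        if np.any(self.S0 < -1e-12) or np.any(self.S0 > self.maxS + 1e-12):
            raise ValueError("S0 must lie in [0, maxS]")
        if len(self.epicenters) > self.max_epicenters:
            raise ValueError("more epicenters than max_epicenters")
        non_epi = np.setdiff1d(np.arange(self.S0.size), np.asarray(self.epicenters, int))
        if np.any(self.S0[non_epi] > self.nonepicenter_ceiling + 1e-12):
            raise ValueError("non-epicenter S0 entries exceed the ceiling")


@dataclass
class ESMState:
    """Simulated trajectory with diagnostic rate decompositions."""

    times: np.ndarray
    S: np.ndarray                    # [N_rois x N_times]
    gini: np.ndarray                 # g(t) per output time
    eps: np.ndarray                  # incoming pressure per region/time
    beta_ext: np.ndarray
    beta_int: np.ndarray


@dataclass
class ESMFit:
    params: ESMParams
    residual_norm: float
    accuracy_percent: float
    effective_production: float
    effective_clearance: float
    candidate_epicenters: list[int]
    simulated: ESMState


def gini_coefficient(S: np.ndarray) -> float:
    """Gini coefficient of a nonnegative regional vector.

    ``g = sum_{i,j} |S_i - S_j| / (2 n^2 mean(S))``; 0 for perfect equality,
    approaching 1 when one region holds everything.  An all-zero vector
    returns 0 by convention.
    """
    x = np.asarray(S, dtype=float).ravel()
    if np.any(x < 0):
        raise ValueError("Gini coefficient requires nonnegative values")
    total = x.sum()
    if total <= 0:
        return 0.0
    n = x.size
    # O(n log n) form of the pairwise absolute-difference sum
    xs = np.sort(x)
    ranks = np.arange(1, n + 1)
    g = (2.0 * np.sum(ranks * xs) - (n + 1) * total) / (n * total)
    return float(max(g, 0.0))


def regional_rates(S: np.ndarray, params: ESMParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-region production and clearance rates at agent levels ``S``."""
    S = np.asarray(S, dtype=float)
    if params.rate_mode == "constant":
        return (np.full_like(S, params.beta_o), np.full_like(S, params.delta_o))
    frac = np.clip(S / params.maxS, 0.0, 1.0)
    beta = 1.0 - np.exp(-params.beta_o * frac)
    delta = np.exp(-params.delta_o * frac)
    return beta, delta


def _esm_rhs(S: np.ndarray, params: ESMParams, weights: np.ndarray,
             diag: np.ndarray) -> np.ndarray:
    S = np.clip(S, 0.0, params.maxS)
    g = gini_coefficient(S)
    beta, delta = regional_rates(S, params)
    beta_ext = g * beta
    beta_int = (1.0 - g) * beta
    off = weights @ (beta_ext * S)  # row i sums Pa[j->i] * beta_j^ext * S_j
    eps = off + diag * beta_int * S
    return (1.0 - S / params.maxS) * eps - delta * S


def _connectome_parts(connectome: Connectome) -> tuple[np.ndarray, np.ndarray]:
    """Split weights into off-diagonal matrix and self-connection vector.

    A zero diagonal would annul the intrinsic term identically, so absent
    self-connections default to 1.
    """
    w = connectome.weights
    diag = np.diag(w).copy()
    if np.all(diag == 0):
        diag = np.ones(w.shape[0])
    off = w.copy()
    np.fill_diagonal(off, 0.0)
    return off, diag


def esm_simulate(
    params: ESMParams,
    connectome: Connectome,
    times: np.ndarray,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> ESMState:
    """Integrate the spreading model from onset over the requested times."""
    times = np.asarray(times, dtype=float)
    if times[0] < params.onset_time - 1e-12:
        raise ValueError("output times must start at or after the onset time")
    if connectome.n_regions != params.S0.size:
        raise ValueError("connectome size does not match S0")
    off, diag = _connectome_parts(connectome)

    def rhs(_t, y):
        return _esm_rhs(y, params, off, diag)

    sol = solve_ivp(
        rhs, (params.onset_time, times[-1]), params.S0,
        t_eval=times, rtol=rtol, atol=atol, method="RK45",
    )
    if not sol.success:
        raise RuntimeError(f"ESM integration failed ({sol.message}); try smaller tolerances")
    S = sol.y
    overshoot = max(float(np.max(S - params.maxS, initial=0.0)),
                    float(np.max(-S, initial=0.0)))
    if overshoot > 1e3 * max(rtol * params.maxS, atol):
        raise RuntimeError("trajectory left [0, maxS] beyond integrator tolerance")
    S = np.clip(S, 0.0, params.maxS)

    g = np.array([gini_coefficient(S[:, k]) for k in range(S.shape[1])])
    beta = np.empty_like(S)
    eps = np.empty_like(S)
    for k in range(S.shape[1]):
        b, _ = regional_rates(S[:, k], params)
        beta[:, k] = b
        eps[:, k] = off @ (g[k] * b * S[:, k]) + diag * (1 - g[k]) * b * S[:, k]
    return ESMState(times=times, S=S, gini=g, eps=eps,
                    beta_ext=g[None, :] * beta, beta_int=(1 - g[None, :]) * beta)


def _backproject_S0(S_first: np.ndarray, t_first: float, t0: float,
                    params: ESMParams, off: np.ndarray, diag: np.ndarray) -> np.ndarray:
    """Integrate backwards from the first observation to the onset time."""
    if t_first <= t0:
        return np.clip(S_first, 0.0, params.maxS)

    def rhs(_t, y):
        return -_esm_rhs(y, params, off, diag)

    sol = solve_ivp(rhs, (0.0, t_first - t0), np.clip(S_first, 0, params.maxS),
                    rtol=1e-6, atol=1e-9)
    if not sol.success:
        return np.clip(S_first, 0.0, params.maxS)
    return np.clip(sol.y[:, -1], 0.0, params.maxS)


def effective_rates(params: ESMParams, n_grid: int = 201) -> tuple[float, float]:
    """Production/clearance rates marginalized over agent levels.

    The state-dependent rates are averaged over a uniform grid of agent
    values on [0, maxS]; in constant mode the constants are returned.
    """
    if params.rate_mode == "constant":
        return float(params.beta_o), float(params.delta_o)
    grid = np.linspace(0.0, params.maxS, n_grid)
    beta, delta = regional_rates(grid, params)
    return float(beta.mean()), float(delta.mean())


def _simulation_grid(t0: float, times: np.ndarray) -> np.ndarray:
    """Dense output grid: onset to last time plus half the observation window."""
    t_end = times[-1] + 0.5 * (times[-1] - times[0])
    dense = np.linspace(t0, t_end, 30 + times.size)
    return np.unique(np.concatenate([dense, times]))


def esm_fit(
    obs: RegionalSeries,
    connectome: Connectome,
    rate_mode: str = "sigmoid",
    max_epicenters: int = 4,
    nonepicenter_ceiling: float | None = None,
    known_epicenters: list[int] | None = None,
    known_onset: float | None = None,
    min_onset: float = 0.0,
    n_starts: int = 32,
    maxS: float | None = None,
    beta_max: float = 10.0,
    delta_max: float = 10.0,
    seed: int = 0,
) -> ESMFit:
    """Fit the spreading model to one subject's longitudinal observations.

    Minimizes the squared misfit summed over regions and time points, by
    bounded nonlinear least squares from ``n_starts`` Latin-hypercube
    starting points over (beta_o, delta_o[, t0]).  For each start the onset
    state is obtained by backward integration from the first observation;
    regions whose back-projected level exceeds the ceiling (at most
    ``max_epicenters``, by rank) become free S0 entries, all others are
    clamped at or below the ceiling.  A minimum of three time points is
    required.
    """
    if len(obs.modalities) != 1:
        raise ValueError("ESM fits a single modality; select one first")
    if obs.n_times < 3:
        raise ValueError(
            f"subject {obs.subject_id}: at least 3 time points are required"
        )
    data = obs.values[:, 0, :]  # [N_rois x N_t]
    times = obs.times
    if maxS is None:
        maxS = float(np.nanmax(data))
    if maxS <= 0:
        raise ValueError("maxS must be positive")
    ceiling = 0.05 * maxS if nonepicenter_ceiling is None else float(nonepicenter_ceiling)
    off, diag = _connectome_parts(connectome)
    n_rois = connectome.n_regions

    free_onset = known_onset is None
    if not free_onset and known_onset > times[0]:
        raise ValueError("onset time must precede the first observation")
    t_first = float(times[0])
    onset_hi = t_first
    onset_lo = min(min_onset, onset_hi)
    if free_onset and onset_hi - onset_lo < 1e-12:
        # degenerate search window: the onset is pinned at the first
        # observation time
        known_onset = onset_lo
        free_onset = False

    sampler = qmc.LatinHypercube(d=3 if free_onset else 2, seed=seed)
    unit = sampler.random(n=n_starts)
    starts = np.empty_like(unit)
    starts[:, 0] = unit[:, 0] * beta_max
    starts[:, 1] = unit[:, 1] * delta_max
    if free_onset:
        starts[:, 2] = onset_lo + unit[:, 2] * (onset_hi - onset_lo)

    finite = np.isfinite(data)
    ss_tot = float(np.sum((data[finite] - data[finite].mean()) ** 2))

    def make_problem(theta0):
        """Freeze the epicenter structure for one start and return residual fn."""
        beta0, delta0 = theta0[0], theta0[1]
        t0 = theta0[2] if free_onset else float(known_onset)
        probe = ESMParams(beta_o=max(beta0, 1e-6), delta_o=max(delta0, 1e-6),
                          S0=np.zeros(n_rois), rate_mode=rate_mode, maxS=maxS,
                          nonepicenter_ceiling=maxS, max_epicenters=n_rois)
        s0_bp = _backproject_S0(data[:, 0], t_first, t0, probe, off, diag)
        if known_epicenters is not None:
            epi = list(known_epicenters)
        else:
            order = np.argsort(-s0_bp)
            epi = [int(i) for i in order[:max_epicenters] if s0_bp[i] > ceiling]
            if not epi:
                epi = [int(order[0])]
        fixed_S0 = np.clip(s0_bp, 0.0, ceiling)

        def unpack(x):
            S0 = fixed_S0.copy()
            S0[epi] = x[2:2 + len(epi)]
            t0_x = x[2 + len(epi)] if free_onset else float(known_onset)
            return ESMParams(
                beta_o=x[0], delta_o=x[1], S0=S0, rate_mode=rate_mode,
                onset_time=t0_x, maxS=maxS, epicenters=epi,
                nonepicenter_ceiling=ceiling, max_epicenters=max(max_epicenters, len(epi)),
            )

        def residuals(x):
            p = unpack(x)
            try:
                state = esm_simulate(p, connectome, times, rtol=1e-6, atol=1e-9)
            except RuntimeError:
                return np.full(finite.sum(), 1e3 * maxS)
            return (state.S - data)[finite]

        x0 = [beta0, delta0] + [float(np.clip(s0_bp[i], ceiling, maxS)) for i in epi]
        lo = [0.0, 0.0] + [0.0] * len(epi)
        hi = [beta_max, delta_max] + [maxS] * len(epi)
        if free_onset:
            x0.append(t0)
            lo.append(onset_lo)
            hi.append(onset_hi)
        return residuals, unpack, np.array(x0), (np.array(lo), np.array(hi))

    best = None
    for theta0 in starts:
        residuals, unpack, x0, bounds = make_problem(theta0)
        try:
            res = least_squares(residuals, x0, bounds=bounds, method="trf",
                                xtol=1e-10, ftol=1e-10, max_nfev=200)
        except Exception:
            continue
        if best is None or res.cost < best[0]:
            best = (res.cost, res.x, unpack)
    if best is None:
        raise RuntimeError("all multistart fits failed")

    _, x_best, unpack = best
    params = unpack(x_best)
    state_obs = esm_simulate(params, connectome, times)
    resid = state_obs.S - data
    resid_norm = float(np.sum(resid[finite] ** 2))
    accuracy = 100.0 * (1.0 - resid_norm / ss_tot) if ss_tot > 0 else np.nan

    ranking = np.argsort(-params.S0)
    eff_prod, eff_clear = effective_rates(params)
    dense = _simulation_grid(params.onset_time, times)
    simulated = esm_simulate(params, connectome, dense)
    return ESMFit(
        params=params,
        residual_norm=resid_norm,
        accuracy_percent=float(accuracy),
        effective_production=eff_prod,
        effective_clearance=eff_clear,
        candidate_epicenters=[int(i) for i in ranking],
        simulated=simulated,
    )


def write_esm_fit(outdir, subject_id: str, fit: ESMFit, prefix: str = "ESM_subject") -> None:
    """Write the documented per-subject ESM output files."""
    from pathlib import Path

    from .io import write_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = outdir / f"{prefix}_{subject_id}"
    write_matrix(f"{base}_ACCURACY.txt", np.array([[fit.accuracy_percent]]))
    write_matrix(f"{base}_resnorm.txt", np.array([[fit.residual_norm]]))
    write_matrix(f"{base}_parameters.txt",
                 np.array([[fit.params.beta_o, fit.params.delta_o]]))
    write_matrix(f"{base}_effective_production.txt",
                 np.array([[fit.effective_production]]))
    write_matrix(f"{base}_effective_clearance.txt",
                 np.array([[fit.effective_clearance]]))
    write_matrix(f"{base}_sorted_most_likely_epicenters.txt",
                 np.array([[i + 1 for i in fit.candidate_epicenters]]))
    write_matrix(f"{base}_S0.txt", fit.params.S0[None, :])
    write_matrix(f"{base}_onset_time.txt", np.array([[fit.params.onset_time]]))
    write_matrix(f"{base}_simulated_data.txt", fit.simulated.S)
    write_matrix(f"{base}_simulated_times.txt", fit.simulated.times[None, :])
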