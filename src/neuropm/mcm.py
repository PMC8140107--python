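"""Multifactorial causal model (MCM).

The brain is modeled as a linear dynamical system over ``N_rois`` regions
times ``N_f`` biological factors (imaging modalities).  The state vector is
factor-major (all regions of factor 1, then factor 2, ...) and holds
*alteration* levels: deviations from a reference pattern.  Its evolution is

    dS/dt = A S + B u,     Cog = beta . S

with the interaction operator assembled from interpretable parameters:

* ``local_interactions[n, m]`` — direct effect of factor n on factor m,
  shared across regions (it acts region-by-region on the diagonal of the
  (m, n) block);
* ``spreading_weights[m]`` — scale of factor-m alteration propagation over
  the physical connectome(s), whose diagonal is zeroed so self-effects live
  only in the local couplings;
* ``network_fractions[m]`` — share of factor-m spreading routed through the
  first connectome (e.g. anatomical) versus the second (e.g. vascular);
* ``input_effects[m]`` — global per-factor gain of the external input.

Fitting offers a spline gradient-matching route (splines through each
regional curve; the operator parameters then solve a ridge-penalized linear
regression in integrated form) and a multistart trajectory-matching route
(bounded nonlinear least squares on the simulated-vs-observed misfit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline, make_smoothing_spline
from scipy.linalg import expm
from scipy.optimize import least_squares

from .io import Connectome, RegionalSeries

__all__ = [
    "MCMParams",
    "MCMOperator",
    "CognitiveModel",
    "MCMFit",
    "build_operator",
    "mcm_simulate",
    "estimate_cognitive_weights",
    "mcm_fit",
    "effective_metrics",
    "to_alterations",
]


@dataclass
class MCMParams:
    local_interactions: np.ndarray          # [N_f x N_f], (n, m) = n -> m
    spreading_weights: np.ndarray           # [N_f] >= 0
    network_fractions: np.ndarray           # [N_f] in [0, 1]
    input_effects: np.ndarray | None = None
    S0_perturbation: np.ndarray | None = None
    perturbation_time: float = 0.0

    def __post_init__(self) -> None:
        self.local_interactions = np.atleast_2d(np.asarray(self.local_interactions, float))
        n_f = self.local_interactions.shape[0]
        if self.local_interactions.shape != (n_f, n_f):
            raise ValueError("local_interactions must be square")
        self.spreading_weights = np.asarray(self.spreading_weights, float).reshape(n_f)
        if np.any(self.spreading_weights < 0):
            raise ValueError("spreading_weights must be nonnegative")
        self.network_fractions = np.asarray(self.network_fractions, float).reshape(n_f)
        if np.any((self.network_fractions < 0) | (self.network_fractions > 1)):
            raise ValueError("network_fractions must lie in [0, 1]")
        if self.input_effects is not None:
            self.input_effects = np.asarray(self.input_effects, float).reshape(n_f)

    @property
    def n_factors(self) -> int:
        return self.local_interactions.shape[0]

    def to_vector(self) -> np.ndarray:
        """Documented flat layout: N_f^2 interactions (row-major, rows =
        source factors, columns = targets), spreading weights, network
        fractions, then input effects when present."""
        parts = [self.local_interactions.ravel(), self.spreading_weights,
                 self.network_fractions]
        if self.input_effects is not None:
            parts.append(self.input_effects)
        return np.concatenate(parts)

    @classmethod
    def from_vector(cls, vec: np.ndarray, n_factors: int,
                    has_input: bool = False) -> "MCMParams":
        vec = np.asarray(vec, float)
        n2 = n_factors * n_factors
        expected = n2 + 2 * n_factors + (n_factors if has_input else 0)
        if vec.size != expected:
            raise ValueError(f"parameter vector length {vec.size}, expected {expected}")
        local = vec[:n2].reshape(n_factors, n_factors)
        spread = vec[n2:n2 + n_factors]
        frac = vec[n2 + n_factors:n2 + 2 * n_factors]
        inp = vec[n2 + 2 * n_factors:] if has_input else None
        return cls(local, spread, frac, inp)


@dataclass
class MCMOperator:
    """Assembled interaction matrix with its building blocks kept around."""

    A: np.ndarray
    n_rois: int
    n_factors: int
    params: MCMParams
    spreading_matrices: list[np.ndarray]    # effective L_m per factor, diag zeroed


@dataclass
class CognitiveModel:
    weights: np.ndarray
    intercept: float = 0.0

    def predict(self, states: np.ndarray) -> np.ndarray:
        return np.asarray(states) @ self.weights + self.intercept


@dataclass
class MCMFit:
    params: MCMParams
    operator: MCMOperator
    residual_norm: float
    accuracy_first: float
    accuracy_last: float
    effective_causality: np.ndarray
    effective_spreading: np.ndarray
    effective_incoming: np.ndarray
    effective_outgoing: np.ndarray
    relative_input_effects: np.ndarray
    simulated_times: np.ndarray
    simulated: np.ndarray                   # [N_rois*N_f x N_times]
    S0: np.ndarray = field(default_factory=lambda: np.array([]))
    obs_times: np.ndarray = field(default_factory=lambda: np.array([]))
    method: str = "spline"


def _mixed_connectome(params: MCMParams, connectomes: list[Connectome],
                      m: int, row_normalize: bool) -> np.ndarray:
    """Effective spreading matrix for factor m, diagonal zeroed."""
    c1 = connectomes[0].weights
    if len(connectomes) == 1:
        L = c1.copy()
    else:
        f = params.network_fractions[m]
        L = f * c1 + (1.0 - f) * connectomes[1].weights
    L = L.copy()
    np.fill_diagonal(L, 0.0)
    if row_normalize:
        sums = L.sum(axis=1, keepdims=True)
        nz = sums[:, 0] > 0
        L[nz] /= sums[nz]
    return L


def build_operator(params: MCMParams, connectomes: Connectome | list[Connectome],
                   row_normalize: bool = False) -> MCMOperator:
    """Assemble the [N_rois*N_f]^2 operator A from interpretable parameters.

    Block (m, n) couples source factor n into target factor m within each
    region (``local_interactions[n, m] * I``); the diagonal block (m, m)
    additionally carries the factor-m spreading term over the mixed
    connectome.  With a single connectome the network fractions are ignored.
    """
    if isinstance(connectomes, Connectome):
        connectomes = [connectomes]
    if not 1 <= len(connectomes) <= 2:
        raise ValueError("provide one or two connectomes")
    n_rois = connectomes[0].n_regions
    for c in connectomes:
        if c.n_regions != n_rois:
            raise ValueError("connectome dimensions disagree")
    n_f = params.n_factors
    eye = np.eye(n_rois)
    A = np.kron(params.local_interactions.T, eye)
    spreading = []
    for m in range(n_f):
        L = _mixed_connectome(params, connectomes, m, row_normalize)
        Lw = params.spreading_weights[m] * L
        spreading.append(Lw)
        A[m * n_rois:(m + 1) * n_rois, m * n_rois:(m + 1) * n_rois] += Lw
    return MCMOperator(A=A, n_rois=n_rois, n_factors=n_f, params=params,
                       spreading_matrices=spreading)


def _input_vector(schedule_row: dict, input_effects: np.ndarray | None,
                  n_rois: int, n_f: int) -> np.ndarray:
    """Constant forcing term for one active schedule row (factor-major)."""
    b = np.zeros(n_rois * n_f)
    gains = input_effects if input_effects is not None else np.ones(n_f)
    for m in range(n_f):
        for i in schedule_row["regions"]:
            if i >= n_rois:
                raise ValueError(f"input schedule targets region {i + 1} > N_rois")
            b[m * n_rois + i] = schedule_row["intensity"] * gains[m]
    return b


def _propagate(A: np.ndarray, S: np.ndarray, b: np.ndarray, dt: float) -> np.ndarray:
    """Exact step of dS/dt = A S + b over dt via an augmented exponential."""
    if dt == 0:
        return S.copy()
    if not np.any(b):
        return expm(A * dt) @ S
    n = A.shape[0]
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = A * dt
    M[:n, n] = b * dt
    E = expm(M)
    return E[:n, :n] @ S + E[:n, n]


def mcm_simulate(
    operator: MCMOperator,
    S0: np.ndarray,
    times: np.ndarray,
    input_schedule: list[dict] | None = None,
    input_effects: np.ndarray | None = None,
    cognitive: CognitiveModel | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Propagate the linear system across ``times`` (matrix exponentials).

    ``input_schedule`` rows are dicts with ``start``, ``stop``, ``intensity``
    and 0-based ``regions`` (see :func:`neuropm.io.read_input_schedule`);
    the input is piecewise constant, so propagation between breakpoints is
    exact.  Returns ``(states [N x N_times], cog or None)``.
    """
    times = np.asarray(times, float)
    S0 = np.asarray(S0, float).reshape(-1)
    if S0.size != operator.A.shape[0]:
        raise ValueError("S0 length does not match operator dimension")
    if input_effects is None:
        input_effects = operator.params.input_effects
    schedule = input_schedule or []
    for row in schedule:
        if row["stop"] < row["start"]:
            raise ValueError("schedule row has stop < start")

    breaks = set(times.tolist())
    for row in schedule:
        for t in (row["start"], row["stop"]):
            if times[0] < t < times[-1]:
                breaks.add(float(t))
    grid = np.array(sorted(breaks))

    def forcing(t_mid: float) -> np.ndarray:
        b = np.zeros(S0.size)
        for row in schedule:
            if row["start"] <= t_mid < row["stop"]:
                b += _input_vector(row, input_effects, operator.n_rois,
                                   operator.n_factors)
        return b

    states_grid = np.empty((S0.size, grid.size))
    states_grid[:, 0] = S0
    S = S0
    for k in range(1, grid.size):
        dt = grid[k] - grid[k - 1]
        b = forcing(0.5 * (grid[k] + grid[k - 1]))
        S = _propagate(operator.A, S, b, dt)
        states_grid[:, k] = S
    sel = np.searchsorted(grid, times)
    states = states_grid[:, sel]
    cog = cognitive.predict(states.T) if cognitive is not None else None
    return states, cog


def estimate_cognitive_weights(states: np.ndarray, scores: np.ndarray) -> CognitiveModel:
    """Population-level linear model Cog = beta . S + c.

    Ordinary least squares when over-determined; otherwise ridge with the
    penalty chosen by generalized cross-validation on an SVD of the centered
    design.
    """
    X = np.atleast_2d(np.asarray(states, float))
    y = np.asarray(scores, float).reshape(-1)
    if X.shape[0] != y.size:
        raise ValueError("states rows must match number of scores")
    if np.ptp(y) == 0:
        warnings.warn("constant cognitive score; returning zero weights")
        return CognitiveModel(weights=np.zeros(X.shape[1]), intercept=float(y[0]))
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    uy = U.T @ yc
    n = y.size
    if n > X.shape[1] and s[-1] > 1e-10 * s[0]:
        w = Vt.T @ (uy / s)
    else:
        lams = np.geomspace(1e-8, 1e4, 61) * (s[0] ** 2 if s[0] > 0 else 1.0)
        best = None
        for lam in lams:
            d = s**2 / (s**2 + lam)
            resid = yc - U @ (d * uy)
            df = d.sum()
            gcv = (resid @ resid) / n / max(1.0 - df / n, 1e-12) ** 2
            if best is None or gcv < best[0]:
                best = (gcv, lam)
        lam = best[1]
        w = Vt.T @ (s * uy / (s**2 + lam))
    return CognitiveModel(weights=w, intercept=float(y_mean - x_mean @ w))


def to_alterations(series: RegionalSeries,
                   reference: np.ndarray | None = None) -> np.ndarray:
    """Alteration states [N_rois x N_f x N_t]: observed minus reference.

    The reference is the mean control baseline pattern when provided,
    otherwise the subject's own first evaluation (which then maps to zero
    alteration).
    """
    vals = series.values
    ref = vals[:, :, 0] if reference is None else np.asarray(reference, float)
    if ref.shape != vals.shape[:2]:
        raise ValueError("reference shape must be [N_rois x N_f]")
    return vals - ref[:, :, None]


def _flatten_states(alter: np.ndarray) -> np.ndarray:
    """[N_rois x N_f x N_t] -> factor-major state matrix [N_rois*N_f x N_t]."""
    n_rois, n_f, n_t = alter.shape
    return alter.transpose(1, 0, 2).reshape(n_rois * n_f, n_t)


def _gcv_lambda_grid(times: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Candidate smoothing penalties and their smoother matrices.

    The penalty is chosen per curve by generalized cross-validation,
    ``GCV(lam) = n RSS / (n - df)^2`` with df the smoother-matrix trace; the
    grid reaches small enough penalties that noiseless curves are fitted
    near-interpolation.
    """
    n = times.size
    span = times[-1] - times[0]
    lams = np.geomspace(1e-10, 1e2, 25) * span**3
    smoothers = []
    eye = np.eye(n)
    for lam in lams:
        S = np.column_stack([
            make_smoothing_spline(times, eye[:, j], lam=lam)(times)
            for j in range(n)
        ])
        smoothers.append(S)
    return lams, smoothers


def _fit_curve_gcv(times: np.ndarray, y: np.ndarray, lams: np.ndarray,
                   smoothers: list[np.ndarray]):
    n = y.size
    best = None
    for lam, S in zip(lams, smoothers):
        df = float(np.trace(S))
        if df > n - 0.5:  # interpolation limit degenerates the GCV score
            continue
        fitted = S @ y
        rss = float(np.sum((y - fitted) ** 2))
        gcv = n * rss / (n - df) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, lam)
    if best is None:
        return make_smoothing_spline(times, y, lam=float(lams[0]))
    return make_smoothing_spline(times, y, lam=best[1])


def _spline_gradient_fit(
    times: np.ndarray,
    alter: np.ndarray,
    connectomes: list[Connectome],
    tikhonov: float,
    u_of_t=None,
    dense_factor: int = 10,
) -> MCMParams:
    """Gradient matching in integrated form: splines -> linear regression.

    A smoothing spline per (region, factor) curve (penalty by GCV) provides
    the state on a dense grid; the dynamics are then imposed in integrated
    (collocation) form — the exactly-observed increments
    ``S(t_{k+1}) - S(t_k)`` regressed on spline-integrated states — which is
    far less sensitive to spline error than derivative matching.  Because
    the response is the exact observed increment, the matching integral uses
    the interpolating spline through the same observed points.  The
    bilinear (spreading weight x network fraction) pair is reparametrized as
    two nonnegative per-connectome weights, making the whole regression
    linear; weights and fractions are recovered afterwards.
    """
    n_rois, n_f, n_t = alter.shape
    dense = np.linspace(times[0], times[-1], dense_factor * n_t)
    # smoothing splines need >= 5 knots; shorter series fall back to the
    # interpolating spline for the dense state as well
    lams, smoothers = _gcv_lambda_grid(times) if n_t >= 5 else (None, None)
    S_hat = np.empty((n_rois, n_f, dense.size))
    # integral of the spline state over every inter-observation interval
    I_hat = np.empty((n_rois, n_f, n_t - 1))
    for i in range(n_rois):
        for m in range(n_f):
            y = alter[i, m, :]
            if np.allclose(y, y[0]):
                S_hat[i, m, :] = y[0]
                I_hat[i, m, :] = y[0] * np.diff(times)
                continue
            interp = CubicSpline(times, y)
            if lams is None:
                S_hat[i, m, :] = interp(dense)
            else:
                spl = _fit_curve_gcv(times, y, lams, smoothers)
                S_hat[i, m, :] = spl(dense)
            I_hat[i, m, :] = np.diff(interp.antiderivative()(times))

    two_nets = len(connectomes) > 1
    nets = []
    for c in connectomes:
        L = c.weights.copy()
        np.fill_diagonal(L, 0.0)
        nets.append(L)

    local = np.zeros((n_f, n_f))
    spread = np.zeros(n_f)
    frac = np.ones(n_f)
    input_eff = np.zeros(n_f) if u_of_t is not None else None
    if u_of_t is not None:
        # integrate the piecewise-constant input over every interval
        U_int = np.zeros((n_rois, n_t - 1))
        for k in range(n_t - 1):
            sub = np.linspace(times[k], times[k + 1], 21)
            Usub = np.stack([u_of_t(t) for t in 0.5 * (sub[1:] + sub[:-1])], axis=1)
            U_int[:, k] = Usub.sum(axis=1) * (sub[1] - sub[0])
    for m in range(n_f):
        cols = [I_hat[:, n, :].ravel() for n in range(n_f)]
        for L in nets:
            cols.append((L @ I_hat[:, m, :]).ravel())
        if u_of_t is not None:
            cols.append(U_int.ravel())
        X = np.column_stack(cols)
        yv = np.diff(alter[:, m, :], axis=1).ravel()
        G = X.T @ X
        if np.trace(G) == 0:  # fully static factor: nothing to identify
            theta = np.zeros(G.shape[0])
        else:
            lam = tikhonov * np.trace(G) / max(G.shape[0], 1)
            theta = np.linalg.solve(G + lam * np.eye(G.shape[0]), X.T @ yv)
        local[:, m] = theta[:n_f]
        w = theta[n_f:n_f + len(nets)]
        w = np.clip(w, 0.0, None)
        if two_nets:
            tot = w.sum()
            spread[m] = tot
            frac[m] = w[0] / tot if tot > 0 else 1.0
        else:
            spread[m] = w[0]
        if u_of_t is not None:
            input_eff[m] = theta[-1]
    return MCMParams(local, spread, frac, input_eff)


def mcm_fit(
    obs: RegionalSeries,
    connectomes: Connectome | list[Connectome],
    method: str = "spline",
    reference: np.ndarray | None = None,
    input_schedule: list[dict] | None = None,
    estimate_S0: bool = False,
    perturbation_time: float | None = None,
    tikhonov: float = 1e-4,
    n_starts: int = 32,
    n_iterations: int = 3,
    local_bound: float | None = None,
    seed: int = 0,
) -> MCMFit:
    """Fit the causal model to one subject's multimodal longitudinal data.

    States are alterations relative to ``reference`` (or the first
    evaluation).  ``method='spline'`` uses gradient matching; `
    `method='multistart'`` minimizes the simulated-vs-observed squared
    misfit from many seeded starts (the spline solution is always included
    as a warm start).  A minimum of three time points is required.
    """
    if isinstance(connectomes, Connectome):
        connectomes = [connectomes]
    if obs.n_times < 3:
        raise ValueError(f"subject {obs.subject_id}: at least 3 time points are required")
    if np.any(~obs.mask):
        raise ValueError(
            f"subject {obs.subject_id}: missing modality values; impute or remove first"
        )
    n_rois = connectomes[0].n_regions
    if obs.n_regions != n_rois:
        raise ValueError("observation region count does not match connectome")
    n_f = len(obs.modalities)
    alter = to_alterations(obs, reference)
    times = obs.times
    states_obs = _flatten_states(alter)     # [N x N_t]
    has_input = input_schedule is not None and len(input_schedule) > 0

    u_of_t = None
    if has_input:
        def u_of_t(t, _sched=input_schedule, _n=n_rois):
            u = np.zeros(_n)
            for row in _sched:
                if row["start"] <= t < row["stop"]:
                    for i in row["regions"]:
                        u[i] += row["intensity"]
            return u

    spline_params = _spline_gradient_fit(times, alter, connectomes, tikhonov, u_of_t)

    def simulate(params: MCMParams) -> np.ndarray:
        op = build_operator(params, connectomes)
        sim, _ = mcm_simulate(op, states_obs[:, 0], times,
                              input_schedule=input_schedule,
                              input_effects=params.input_effects)
        return sim

    if method == "spline":
        params = spline_params
    elif method == "multistart":
        scale = float(np.max(np.abs(states_obs))) or 1.0
        if local_bound is None:
            # generous dynamic-rate bound from the data's own time scale
            local_bound = 10.0 / max(times[-1] - times[0], 1e-12)
        two_nets = len(connectomes) > 1
        n2 = n_f * n_f

        def pack(p: MCMParams) -> np.ndarray:
            v = [p.local_interactions.ravel(), p.spreading_weights]
            if two_nets:
                v.append(p.network_fractions)
            if has_input:
                v.append(p.input_effects if p.input_effects is not None
                         else np.zeros(n_f))
            return np.concatenate(v)

        def unpack(x: np.ndarray) -> MCMParams:
            local = x[:n2].reshape(n_f, n_f)
            spread = x[n2:n2 + n_f]
            k = n2 + n_f
            if two_nets:
                frac = x[k:k + n_f]
                k += n_f
            else:
                frac = np.ones(n_f)
            inp = x[k:k + n_f] if has_input else None
            return MCMParams(local, np.clip(spread, 0, None),
                             np.clip(frac, 0, 1), inp)

        def residuals(x: np.ndarray) -> np.ndarray:
            try:
                sim = simulate(unpack(x))
            except (ValueError, np.linalg.LinAlgError):
                return np.full(states_obs.size, 1e3 * scale)
            r = sim - states_obs
            if not np.all(np.isfinite(r)):
                return np.full(states_obs.size, 1e3 * scale)
            return r.ravel()

        dim = n2 + n_f + (n_f if two_nets else 0) + (n_f if has_input else 0)
        lo = np.concatenate([
            -local_bound * np.ones(n2), np.zeros(n_f),
            np.zeros(n_f) if two_nets else np.empty(0),
            -local_bound * np.ones(n_f) if has_input else np.empty(0)])
        hi = np.concatenate([
            local_bound * np.ones(n2), local_bound * np.ones(n_f),
            np.ones(n_f) if two_nets else np.empty(0),
            local_bound * np.ones(n_f) if has_input else np.empty(0)])

        rng = np.random.default_rng(seed)
        x_warm = np.clip(pack(spline_params), lo, hi)
        best = None
        for _ in range(max(1, n_iterations)):
            starts = [x_warm] + [lo + rng.random(dim) * (hi - lo)
                                 for _ in range(max(0, n_starts - 1))]
            for x0 in starts:
                try:
                    res = least_squares(residuals, x0, bounds=(lo, hi),
                                        method="trf", xtol=1e-12, ftol=1e-12,
                                        max_nfev=120)
                except Exception:
                    continue
                if best is None or res.cost < best[0]:
                    best = (res.cost, res.x)
            if best is not None:
                x_warm = best[1]
        if best is None:
            raise RuntimeError("all multistart fits failed")
        params = unpack(best[1])
    else:
        raise ValueError(f"unknown method {method!r}")

    operator = build_operator(params, connectomes)
    sim = simulate(params)
    resid = sim - states_obs
    resid_norm = float(np.sum(resid**2))

    def acc(k: int) -> float:
        sstot = float(np.sum((states_obs[:, k] - states_obs[:, k].mean()) ** 2))
        ssres = float(np.sum(resid[:, k] ** 2))
        return 100.0 * (1.0 - ssres / sstot) if sstot > 0 else np.nan

    eff = effective_metrics(params, connectomes, alter,
                            input_schedule=input_schedule)

    t_start = times[0]
    if estimate_S0:
        t_p = perturbation_time if perturbation_time is not None else times[0]
        if t_p > times[0]:
            raise ValueError("perturbation time must precede the first observation")
        S0_est = expm(operator.A * (t_p - times[0])) @ states_obs[:, 0]
        params.S0_perturbation = S0_est
        params.perturbation_time = float(t_p)
        t_start = t_p
    dense = np.unique(np.concatenate([
        np.linspace(t_start, times[-1] + 0.5 * (times[-1] - times[0]),
                    30 + times.size), times]))
    S_dense0 = (params.S0_perturbation if estimate_S0 else states_obs[:, 0])
    op_for_dense = operator
    sim_dense, _ = mcm_simulate(op_for_dense, S_dense0,
                                dense if estimate_S0 else dense[dense >= times[0]],
                                input_schedule=input_schedule,
                                input_effects=params.input_effects)
    dense_times = dense if estimate_S0 else dense[dense >= times[0]]

    return MCMFit(
        params=params, operator=operator, residual_norm=resid_norm,
        accuracy_first=acc(0), accuracy_last=acc(times.size - 1),
        effective_causality=eff["causality"],
        effective_spreading=eff["spreading"],
        effective_incoming=eff["incoming"],
        effective_outgoing=eff["outgoing"],
        relative_input_effects=eff["input"],
        simulated_times=dense_times, simulated=sim_dense,
        S0=states_obs[:, 0].copy(), obs_times=times.copy(), method=method,
    )


def effective_metrics(
    params: MCMParams,
    connectomes: Connectome | list[Connectome],
    states: np.ndarray,
    input_schedule: list[dict] | None = None,
    times: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Relative (percent) decomposition of each factor's modeled change.

    For every target factor m the absolute modeled contributions — direct
    effects of each source factor, connectome spreading, and external input
    — are accumulated over regions and observed times; each is then
    expressed as a percentage of their total, so per target factor the
    direct, spreading and input shares sum to 100.
    """
    if isinstance(connectomes, Connectome):
        connectomes = [connectomes]
    states = np.asarray(states, float)
    if states.ndim != 3:
        raise ValueError("states must be [N_rois x N_f x N_t]")
    n_rois, n_f, n_t = states.shape
    causality = np.zeros((n_f, n_f))
    spreading = np.zeros(n_f)
    input_share = np.zeros(n_f)
    num_local = np.zeros((n_f, n_f))
    num_spread = np.zeros(n_f)
    num_input = np.zeros(n_f)
    dens = np.zeros(n_f)

    for m in range(n_f):
        L = params.spreading_weights[m] * _mixed_connectome(
            params, connectomes, m, row_normalize=False)
        for n in range(n_f):
            num_local[n, m] = np.sum(np.abs(params.local_interactions[n, m]
                                            * states[:, n, :]))
        num_spread[m] = np.sum(np.abs(L @ states[:, m, :]))
        if input_schedule and params.input_effects is not None:
            tgrid = times if times is not None else np.arange(n_t, dtype=float)
            for k, t in enumerate(tgrid):
                for row in input_schedule:
                    if row["start"] <= t < row["stop"]:
                        num_input[m] += (len(row["regions"])
                                         * abs(params.input_effects[m]
                                               * row["intensity"]))
        dens[m] = num_local[:, m].sum() + num_spread[m] + num_input[m]
        if dens[m] <= 0:
            warnings.warn(f"factor {m}: all contributions are zero; metrics set to 0")
            continue
        causality[:, m] = 100.0 * num_local[:, m] / dens[m]
        spreading[m] = 100.0 * num_spread[m] / dens[m]
        input_share[m] = 100.0 * num_input[m] / dens[m]

    incoming = np.array([causality[:, m].sum() - causality[m, m]
                         for m in range(n_f)])
    outgoing = np.zeros(n_f)
    for n in range(n_f):
        num = sum(num_local[n, m] for m in range(n_f) if m != n)
        den = sum(dens[m] for m in range(n_f) if m != n)
        outgoing[n] = 100.0 * num / den if den > 0 else 0.0
    return {"causality": causality, "spreading": spreading,
            "incoming": incoming, "outgoing": outgoing, "input": input_share}


def write_mcm_fit(outdir, subject_id: str, fit: MCMFit,
                  prefix: str = "MCM_subject") -> None:
    """Write the documented per-subject MCM output files."""
    from pathlib import Path

    from .io import write_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = outdir / f"{prefix}_{subject_id}"
    write_matrix(f"{base}_accuracy_resnorm.txt",
                 np.array([[fit.accuracy_first, fit.accuracy_last,
                            fit.residual_norm]]))
    write_matrix(f"{base}_parameters.txt", fit.params.to_vector()[None, :])
    write_matrix(f"{base}_Effective_causality.txt", fit.effective_causality)
    write_matrix(f"{base}_Effective_spreading.txt",
                 fit.effective_spreading[None, :])
    write_matrix(f"{base}_Effective_incoming.txt",
                 fit.effective_incoming[None, :])
    write_matrix(f"{base}_Effective_outgoing.txt",
                 fit.effective_outgoing[None, :])
    write_matrix(f"{base}_A_networks_optimum.txt", fit.operator.A)
    if fit.params.S0_perturbation is not None:
        write_matrix(f"{base}_initial_perturbation.txt",
                     fit.params.S0_perturbation[None, :])
        write_matrix(f"{base}_perturbation_time.txt",
                     np.array([[fit.params.perturbation_time]]))
        if fit.obs_times.size:
            pre = fit.simulated_times < fit.obs_times[0]
            if pre.any():
                write_matrix(f"{base}_est_data_before_perturbation.txt",
                             fit.simulated[:, pre])
    inp = (fit.params.input_effects if fit.params.input_effects is not None
           else np.zeros(fit.params.n_factors))
    write_matrix(f"{base}_intervention_effects.txt", inp[None, :])
    write_matrix(f"{base}_relative_intervention_effects.txt",
                 fit.relative_input_effects[None, :])
    write_matrix(f"{base}_simulated_data.txt", fit.simulated)
    write_matrix(f"{base}_simulated_times.txt", fit.simulated_times[None, :])
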