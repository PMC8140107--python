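"""Synthetic cohorts and ground-truth trajectories for every engine.

Three generators cover the package's inputs end to end:

* ``generate_zscore_cohort`` — cross-sectional subtype cohorts following a
  linear z-score event model: each informative biomarker crosses successive
  z thresholds at subtype-specific ordered positions along a latent disease
  stage, one subtype acting as the near-stage-zero control group;
* ``generate_connectome`` — connected random weighted graphs standing in
  for anatomical/vascular connectomes;
* ``generate_esm_dataset`` / ``generate_mcm_dataset`` — longitudinal
  regional observations simulated from known spreading / causal-model
  parameters plus observation noise, for parameter-recovery studies.

All generators are deterministic given their seed; per-subject streams are
spawned from (seed, subject index) so regeneration order does not matter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components

from .esm import ESMParams, esm_simulate
from .io import Connectome, FeatureTable, RegionalSeries
from .mcm import MCMParams, build_operator, mcm_simulate

__all__ = [
    "ZScoreCohortSpec",
    "generate_zscore_cohort",
    "generate_connectome",
    "generate_esm_dataset",
    "generate_mcm_dataset",
]


@dataclass
class ZScoreCohortSpec:
    """Design of a z-score subtype cohort.

    ``n_subtypes`` counts the control group plus the diseased subtypes
    (3 means one control + two diseased).  Disease stages are uniform on
    [0, 1]; control stages are compressed to [0, 0.05].  Informative
    biomarkers follow the subtype's event trajectory plus Gaussian noise;
    the remaining biomarkers are pure standard-normal noise.
    """

    n_subtypes: int = 3
    n_subjects: int = 500
    n_informative: int = 50
    n_noise: int = 50
    noise_sd: float = 1.0
    z_events: tuple[float, ...] = (1.0, 2.0, 3.0)
    z_max: float = 5.0
    control_stage_max: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subtypes < 2:
            raise ValueError("need at least one control and one diseased subtype")
        if self.n_informative < 1 or self.n_noise < 0:
            raise ValueError("invalid feature counts")


def _event_positions(rng: np.random.Generator, n_biomarkers: int,
                     n_levels: int) -> np.ndarray:
    """Random monotonic event ordering -> positions in (0, 1).

    A uniformly random permutation of all (biomarker, z-level) events is
    drawn, then each biomarker's own events are sorted ascending — a
    uniformly random ordering among the monotone ones.  Event ranks map to
    positions rank/(N_events + 1).
    """
    n_events = n_biomarkers * n_levels
    perm = rng.permutation(n_events)
    ranks = perm.reshape(n_biomarkers, n_levels)
    ranks = np.sort(ranks, axis=1)
    return (ranks + 1) / (n_events + 1)


def _trajectory(stage: float, positions: np.ndarray,
                z_levels: tuple[float, ...], z_max: float) -> float:
    """Piecewise-linear z trajectory through the biomarker's event points.

    After the last event the biomarker keeps rising linearly toward
    ``z_max`` at stage 1, as in the linear z-score event-model family.
    """
    xs = np.concatenate([[0.0], positions, [1.0]])
    ys = np.concatenate([[0.0], np.asarray(z_levels, float), [z_max]])
    return float(np.interp(stage, xs, ys))


def generate_zscore_cohort(spec: ZScoreCohortSpec) -> tuple[FeatureTable, dict]:
    """Simulate a subtype cohort; returns (table, ground_truth).

    ``ground_truth`` carries per-subject ``stage`` and ``subtype`` (0 =
    control) plus the informative/noise feature index lists and the event
    positions per diseased subtype.
    """
    rng = np.random.default_rng([spec.seed, 0])
    n_dis = spec.n_subtypes - 1
    positions = [
        _event_positions(np.random.default_rng([spec.seed, 1000 + s]),
                         spec.n_informative, len(spec.z_events))
        for s in range(n_dis)
    ]
    n = spec.n_subjects
    subtype = rng.integers(0, spec.n_subtypes, size=n)
    stage = np.empty(n)
    p = spec.n_informative + spec.n_noise
    values = np.empty((n, p))
    for i in range(n):
        r = np.random.default_rng([spec.seed, 2, i])
        if subtype[i] == 0:
            stage[i] = r.uniform(0.0, spec.control_stage_max)
            traj = positions[r.integers(0, n_dis)]
        else:
            stage[i] = r.uniform(0.0, 1.0)
            traj = positions[subtype[i] - 1]
        for b in range(spec.n_informative):
            values[i, b] = (_trajectory(stage[i], traj[b], spec.z_events,
                                        spec.z_max)
                            + r.normal(0.0, spec.noise_sd))
        values[i, spec.n_informative:] = r.normal(0.0, 1.0, size=spec.n_noise)

    ids = [str(i + 1) for i in range(n)]
    names = ([f"informative{b + 1}" for b in range(spec.n_informative)]
             + [f"noise{b + 1}" for b in range(spec.n_noise)])
    bg = [ids[i] for i in range(n) if subtype[i] == 0]
    tg = [ids[i] for i in range(n) if subtype[i] != 0]
    table = FeatureTable(values=values, subject_ids=ids, feature_names=names,
                         background_ids=bg, target_ids=tg)
    truth = {
        "stage": stage,
        "subtype": subtype,
        "informative": np.arange(spec.n_informative),
        "noise": np.arange(spec.n_informative, p),
        "event_positions": positions,
    }
    return table, truth


def generate_connectome(
    n_regions: int,
    density: float = 0.3,
    weight_distribution: str = "lognormal",
    symmetric: bool = True,
    seed: int = 0,
    name: str = "anatomical",
) -> Connectome:
    """Connected random weighted graph with zero diagonal.

    Edges follow an Erdos-Renyi mask at the requested density with weights
    drawn from the stated distribution; disconnected draws are resampled
    (up to 100 tries).
    """
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    for _ in range(100):
        mask = rng.random((n_regions, n_regions)) < density
        if weight_distribution == "lognormal":
            w = rng.lognormal(0.0, 0.5, size=(n_regions, n_regions))
        elif weight_distribution == "uniform":
            w = rng.uniform(0.1, 1.0, size=(n_regions, n_regions))
        else:
            raise ValueError(f"unknown weight_distribution {weight_distribution!r}")
        W = np.where(mask, w, 0.0)
        np.fill_diagonal(W, 0.0)
        if symmetric:
            W = np.triu(W, 1)
            W = W + W.T
        n_comp, _ = connected_components(W > 0, directed=False)
        if n_comp == 1:
            return Connectome(W, name=name)
    raise RuntimeError("could not draw a connected graph in 100 tries; raise density")


def generate_esm_dataset(
    params: ESMParams,
    connectome: Connectome,
    observation_times: np.ndarray,
    noise_sd: float = 0.0,
    n_subjects: int = 1,
    seed: int = 0,
    rate_jitter: float = 0.0,
) -> tuple[list[RegionalSeries], list[ESMParams]]:
    """Simulate noisy spreading-model observations for a synthetic cohort.

    Each subject shares the template parameters, optionally with relative
    lognormal-free jitter (``rate_jitter``) on beta_o/delta_o and a
    subject-specific epicenter; Gaussian observation noise is added and the
    result clipped to [0, maxS].
    """
    times = np.asarray(observation_times, float)
    cohort, truths = [], []
    for i in range(n_subjects):
        rng = np.random.default_rng([seed, i])
        beta_o = params.beta_o * (1.0 + rate_jitter * rng.uniform(-1, 1))
        delta_o = params.delta_o * (1.0 + rate_jitter * rng.uniform(-1, 1))
        p_i = ESMParams(
            beta_o=beta_o, delta_o=delta_o, S0=params.S0.copy(),
            rate_mode=params.rate_mode, onset_time=params.onset_time,
            maxS=params.maxS, epicenters=list(params.epicenters),
            nonepicenter_ceiling=params.nonepicenter_ceiling,
            max_epicenters=params.max_epicenters,
        )
        state = esm_simulate(p_i, connectome, times)
        obs = state.S + rng.normal(0.0, noise_sd, size=state.S.shape)
        obs = np.clip(obs, 0.0, params.maxS)
        cohort.append(RegionalSeries(
            subject_id=str(i + 1), modalities=["agent"], times=times,
            values=obs[:, None, :]))
        truths.append(p_i)
    return cohort, truths


def generate_mcm_dataset(
    params: MCMParams,
    connectomes: Connectome | list[Connectome],
    observation_times: np.ndarray,
    noise_sd: float = 0.0,
    n_subjects: int = 1,
    seed: int = 0,
    S0: np.ndarray | None = None,
    S0_jitter: float = 0.0,
    input_schedule: list[dict] | None = None,
    max_spectral_abscissa: float = 5.0,
) -> tuple[list[RegionalSeries], dict]:
    """Simulate noisy multimodal alteration trajectories from known params.

    The spectral abscissa (largest real part of the operator's eigenvalues)
    must stay below ``max_spectral_abscissa`` so trajectories remain at desk
    scale over the observation window.
    """
    if isinstance(connectomes, Connectome):
        connectomes = [connectomes]
    op = build_operator(params, connectomes)
    abscissa = float(np.max(np.linalg.eigvals(op.A).real))
    if abscissa > max_spectral_abscissa:
        raise ValueError(
            f"operator spectral abscissa {abscissa:.3g} exceeds "
            f"{max_spectral_abscissa}; rescale the parameters")
    times = np.asarray(observation_times, float)
    n_rois, n_f = op.n_rois, op.n_factors
    if S0 is None:
        S0 = params.S0_perturbation
    if S0 is None:
        raise ValueError("provide S0 or set params.S0_perturbation")
    S0 = np.asarray(S0, float).reshape(-1)

    cohort = []
    for i in range(n_subjects):
        rng = np.random.default_rng([seed, i])
        s0_i = S0 * (1.0 + S0_jitter * rng.uniform(-1, 1, size=S0.size))
        sim, _ = mcm_simulate(op, s0_i, times, input_schedule=input_schedule,
                              input_effects=params.input_effects)
        sim = sim + rng.normal(0.0, noise_sd, size=sim.shape)
        # factor-major flat state back to [N_rois x N_f x N_t]
        vals = sim.reshape(n_f, n_rois, times.size).transpose(1, 0, 2)
        cohort.append(RegionalSeries(
            subject_id=str(i + 1),
            modalities=[f"factor_{m + 1}" for m in range(n_f)],
            times=times, values=vals))
    truth = {"params": params, "operator": op, "S0": S0,
             "input_schedule": input_schedule}
    return cohort, truth
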