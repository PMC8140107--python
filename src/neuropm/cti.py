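"""Contrastive trajectory inference (cTI).

Orders cross-sectional subjects along a disease-progression axis by
contrasting a target population (e.g. patients) against a background
population (e.g. matched healthy subjects):

1. optional covariate adjustment with robust additive linear models
   including pairwise interactions;
2. optional unsupervised feature preselection comparing sample variance
   against neighborhood variance;
3. Box-Cox transformation and z-scoring of every feature;
4. contrastive PCA — eigenvectors of ``C_target - alpha * C_background``
   over a grid of contrast strengths, with the candidate subspaces
   clustered by principal-angle affinity and the winner chosen by the
   concentration of its contrast spectrum;
5. pseudotimes as minimum-spanning-tree distances to the background
   centroid (normalized to [0, 1]), subtrajectories by a BIC-selected
   Gaussian mixture over the variance-equalized contrasted scores, and
   per-feature contribution scores from the eigenvalue-weighted squared
   loadings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra, minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform
from scipy.stats import boxcox
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors

from .io import FeatureTable

__all__ = [
    "CPCAModel",
    "TrajectoryResult",
    "adjust_covariates",
    "preselect_features",
    "boxcox_standardize",
    "cpca_decompose",
    "compute_pseudotimes",
    "assign_subtrajectories",
    "feature_contributions",
    "run_cti",
]


@dataclass
class CPCAModel:
    """Fitted contrastive-PCA decomposition.

    ``loadings`` holds all ``N_total`` orthonormal eigenvectors of the
    selected contrast ``C_target - alpha * C_background``, eigenvalues
    sorted descending.  ``normalized_eigenvalues`` are shifted by the
    minimum eigenvalue and sum to one; ``n_cpc`` counts those above
    ``eigenvalue_cutoff``.
    """

    alphas: np.ndarray
    selected_alpha: float
    loadings: np.ndarray              # [n_features x N_total]
    eigenvalues: np.ndarray
    normalized_eigenvalues: np.ndarray
    eigenvalue_cutoff: float = 0.025

    @property
    def n_cpc(self) -> int:
        return int(np.sum(self.normalized_eigenvalues > self.eigenvalue_cutoff))

    def transform(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        k = self.n_cpc if n_components is None else n_components
        return np.asarray(X, float) @ self.loadings[:, :k]


@dataclass
class TrajectoryResult:
    pseudotimes: np.ndarray
    memberships: list[list[int]]      # per subject, most- to least-probable
    n_subtrajectories: int
    contributions: np.ndarray
    preselected_indices: np.ndarray | None = None
    model: CPCAModel | None = None
    scores: np.ndarray | None = None
    subject_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# (i) covariate adjustment
# ---------------------------------------------------------------------------

def _expand_covariates(cov: np.ndarray, names: list[str],
                       categorical_threshold: int = 7
                       ) -> tuple[np.ndarray, list[str]]:
    """Expand near-discrete covariates into one indicator column per level."""
    cols, out_names = [], []
    for j in range(cov.shape[1]):
        c = cov[:, j]
        levels = np.unique(c)
        if levels.size < categorical_threshold:
            for lev in levels:
                cols.append((c == lev).astype(float))
                out_names.append(f"{names[j]}=={lev:g}")
        else:
            cols.append(c.astype(float))
            out_names.append(names[j])
    return np.column_stack(cols), out_names


def _design_with_interactions(expanded: np.ndarray, groups: list[int]
                              ) -> np.ndarray:
    """Main effects plus pairwise products across distinct covariates."""
    cols = [np.ones(expanded.shape[0])] + [expanded[:, j] for j in range(expanded.shape[1])]
    for a in range(expanded.shape[1]):
        for b in range(a + 1, expanded.shape[1]):
            if groups[a] != groups[b]:
                cols.append(expanded[:, a] * expanded[:, b])
    X = np.column_stack(cols)
    # drop aliased (linearly dependent) columns via rank-revealing QR
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-8 * max(np.abs(np.diag(r)).max(), 1e-300)
    if not keep.all():
        warnings.warn(f"dropping {np.sum(~keep)} aliased design column(s)")
        X = X[:, keep]
    return X


def adjust_covariates(table: FeatureTable,
                      categorical_threshold: int = 7) -> FeatureTable:
    """Residualize each feature on the covariates with robust regression.

    The design contains an intercept, main effects and all pairwise
    interactions between distinct covariates; covariates with fewer than
    ``categorical_threshold`` unique values are expanded to one indicator
    per level.  Fits use iteratively reweighted least squares with Huber
    weights, and residuals are re-centered to each feature's original mean.
    """
    if table.covariates is None:
        raise ValueError("table has no covariates to adjust for")
    import statsmodels.api as sm

    expanded, exp_names = _expand_covariates(table.covariates,
                                             list(table.covariate_names),
                                             categorical_threshold)
    groups = []
    for j, nm in enumerate(exp_names):
        base = nm.split("==")[0]
        groups.append(list(table.covariate_names).index(base))
    X = _design_with_interactions(expanded, groups)
    if table.n_subjects <= X.shape[1]:
        raise ValueError(
            f"{table.n_subjects} subjects for {X.shape[1]} expanded covariate terms"
        )
    adjusted = np.empty_like(table.values)
    for f in range(table.n_features):
        y = table.values[:, f]
        try:
            fit = sm.RLM(y, X, M=sm.robust.norms.HuberT()).fit()
            resid = y - fit.fittedvalues
        except Exception:
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
        adjusted[:, f] = resid - resid.mean() + y.mean()
    return FeatureTable(
        values=adjusted, subject_ids=list(table.subject_ids),
        feature_names=list(table.feature_names), covariates=table.covariates,
        covariate_names=list(table.covariate_names),
        background_ids=list(table.background_ids),
        target_ids=list(table.target_ids),
    )


# ---------------------------------------------------------------------------
# (ii) feature preselection
# ---------------------------------------------------------------------------

def preselect_features(table: FeatureTable | np.ndarray,
                       keep_fraction: float = 0.05,
                       k_neighbors: int = 10) -> np.ndarray:
    """Rank features by sample variance minus neighborhood variance.

    The neighborhood variance of a feature is the mean squared difference
    between each subject's value and the values of its k nearest neighbors
    in the full feature space; features varying smoothly along a latent
    ordering score high, unstructured features score at or below zero.
    Zero-variance features rank last.  Returns the indices of the top
    ``ceil(keep_fraction * n_features)`` features, in score order.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must lie in (0, 1]")
    X = table.values if isinstance(table, FeatureTable) else np.asarray(table, float)
    n, p = X.shape
    if n <= k_neighbors:
        raise ValueError("need more subjects than k_neighbors")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    _, idx = nn.kneighbors(X)
    neigh = idx[:, 1:]                                   # drop self
    diffs = X[:, None, :] - X[neigh, :]                  # [n x k x p]
    neigh_var = np.mean(diffs**2, axis=(0, 1))
    sample_var = X.var(axis=0, ddof=1)
    score = sample_var - neigh_var
    score[sample_var == 0] = -np.inf                     # constants rank last
    order = np.argsort(-score, kind="stable")
    n_keep = int(np.ceil(keep_fraction * p))
    return order[:n_keep]


# ---------------------------------------------------------------------------
# (iii) Box-Cox standardization
# ---------------------------------------------------------------------------

def boxcox_standardize(values: np.ndarray) -> np.ndarray:
    """Box-Cox transform (ML lambda) then z-score every feature.

    Non-positive features are shifted by ``1 - min`` first.  Zero-variance
    features are flagged and set to zero.
    """
    X = np.asarray(values, float).copy()
    out = np.empty_like(X)
    for f in range(X.shape[1]):
        y = X[:, f]
        if np.ptp(y) == 0:
            warnings.warn(f"feature {f} has zero variance; set to 0")
            out[:, f] = 0.0
            continue
        if y.min() <= 0:
            y = y + (1.0 - y.min())
        t, _ = boxcox(y)
        sd = t.std(ddof=0)
        out[:, f] = (t - t.mean()) / sd if sd > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# (iii) contrastive PCA
# ---------------------------------------------------------------------------

def _principal_angle_affinity(subspaces: list[np.ndarray]) -> np.ndarray:
    """Pairwise affinity = mean squared cosine of the principal angles."""
    n = len(subspaces)
    aff = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            sv = np.linalg.svd(subspaces[a].T @ subspaces[b], compute_uv=False)
            val = float(np.mean(np.clip(sv, 0, 1) ** 2))
            aff[a, b] = aff[b, a] = val
    return aff


def hopkins_statistic(X: np.ndarray, rng: np.random.Generator,
                      m: int | None = None) -> float:
    """Hopkins clustering-tendency statistic in [0, 1] (0.5 = uniform)."""
    X = np.atleast_2d(np.asarray(X, float))
    n = X.shape[0]
    if m is None:
        m = min(50, max(2, n // 10))
    sample_idx = rng.choice(n, size=m, replace=False)
    lo, hi = X.min(axis=0), X.max(axis=0)
    uniform = rng.uniform(lo, hi, size=(m, X.shape[1]))
    nn = NearestNeighbors(n_neighbors=2).fit(X)
    w = nn.kneighbors(X[sample_idx])[0][:, 1]            # skip the point itself
    u = nn.kneighbors(uniform, n_neighbors=1)[0][:, 0]
    denom = u.sum() + w.sum()
    return float(u.sum() / denom) if denom > 0 else 0.5


def _spectral_cluster_affinity(affinity: np.ndarray, n_clusters: int,
                               seed: int = 0) -> np.ndarray:
    """Normalized-Laplacian spectral clustering on a precomputed affinity."""
    d = affinity.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(np.maximum(d, 1e-300))
    L = np.eye(affinity.shape[0]) - d_inv_sqrt[:, None] * affinity * d_inv_sqrt[None, :]
    evals, evecs = np.linalg.eigh(L)
    emb = evecs[:, :n_clusters]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    emb = emb / np.maximum(norms, 1e-300)
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    return km.fit_predict(emb)


def cpca_decompose(
    target: np.ndarray,
    background: np.ndarray,
    n_alphas: int = 100,
    alpha_range: tuple[float, float] = (1e-2, 1e2),
    max_components: int | None = None,
    alphas: np.ndarray | None = None,
    n_subspace_clusters: int = 4,
    eigenvalue_cutoff: float = 0.025,
    seed: int = 0,
) -> CPCAModel:
    """Contrastive PCA with automatic contrast-strength selection.

    For every alpha on a log-spaced grid the top eigenvectors of
    ``C_target - alpha * C_background`` define a candidate subspace; the
    candidates are clustered by principal-angle affinity (spectral
    clustering into a handful of representatives) and the representative
    whose target projection shows the largest clustering-tendency gain over
    the background projection (Hopkins statistic difference) wins.
    """
    T = np.atleast_2d(np.asarray(target, float))
    Bg = np.atleast_2d(np.asarray(background, float))
    if T.shape[1] != Bg.shape[1]:
        raise ValueError("target and background must share feature columns")
    if T.shape[0] < 2 or Bg.shape[0] < 2:
        raise ValueError("need at least two rows in target and background")
    p = T.shape[1]
    if max_components is None:
        max_components = min(10, p)
    if max_components > p:
        warnings.warn("max_components exceeds feature count; clipped")
        max_components = p
    if alphas is None:
        alphas = np.logspace(np.log10(alpha_range[0]), np.log10(alpha_range[1]),
                             n_alphas)
    alphas = np.asarray(alphas, float)

    C_t = np.cov(T, rowvar=False)
    C_b = np.cov(Bg, rowvar=False)

    def decompose(alpha: float) -> tuple[np.ndarray, np.ndarray]:
        evals, evecs = np.linalg.eigh(C_t - alpha * C_b)
        order = np.argsort(-evals)
        return evals[order], evecs[:, order]

    subspaces = []
    for a in alphas:
        _, vecs = decompose(a)
        subspaces.append(vecs[:, :max_components])

    if alphas.size == 1:
        selected_alpha = float(alphas[0])
    else:
        n_clusters = min(n_subspace_clusters, alphas.size)
        aff = _principal_angle_affinity(subspaces)
        labels = _spectral_cluster_affinity(aff, n_clusters, seed=seed)
        best = None
        for c in range(n_clusters):
            members = np.nonzero(labels == c)[0]
            if members.size == 0:
                continue
            # medoid: most central alpha of the cluster
            med = members[np.argmax(aff[np.ix_(members, members)].sum(axis=1))]
            evals_m, _ = decompose(float(alphas[med]))
            shifted = evals_m - evals_m.min()
            tot = shifted.sum()
            # spectral concentration: a genuine contrast packs the
            # target-enriched variance into few directions, whereas a
            # contrast dominated by background sampling noise spreads it
            # thin across the whole spectrum
            score = float(shifted[0] / tot) if tot > 0 else 0.0
            if best is None or score > best[0]:
                best = (score, float(alphas[med]))
        selected_alpha = best[1]

    evals, evecs = decompose(selected_alpha)
    # orient each loading column so its largest-magnitude entry is positive
    flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0), np.arange(p)])
    flip[flip == 0] = 1.0
    evecs = evecs * flip[None, :]
    shifted = evals - evals.min()
    total = shifted.sum()
    lam_norm = shifted / total if total > 0 else np.full(p, 1.0 / p)
    return CPCAModel(
        alphas=alphas, selected_alpha=selected_alpha, loadings=evecs,
        eigenvalues=evals, normalized_eigenvalues=lam_norm,
        eigenvalue_cutoff=eigenvalue_cutoff,
    )


# ---------------------------------------------------------------------------
# (iv) pseudotimes and subtrajectories
# ---------------------------------------------------------------------------

def compute_pseudotimes(cpc_scores: np.ndarray,
                        background_index: np.ndarray,
                        jitter_seed: int = 0) -> np.ndarray:
    """Minimum-spanning-tree distance to the background centroid, in [0, 1].

    A virtual centroid node (coordinate-wise mean of the background scores)
    joins the subjects; the MST of the Euclidean distance graph is built and
    each subject's pseudotime is its tree-path length to the centroid,
    normalized by the population maximum.
    """
    X = np.atleast_2d(np.asarray(cpc_scores, float))
    bg = np.asarray(background_index, int)
    if bg.size < 1:
        raise ValueError("at least one background subject is required")
    centroid = X[bg].mean(axis=0)
    pts = np.vstack([X, centroid])
    # duplicated coordinates break MST-path uniqueness; nudge deterministically
    d = squareform(pdist(pts))
    dup = (d + np.eye(d.shape[0])) == 0
    if dup.any():
        warnings.warn("duplicate coordinates; applying infinitesimal jitter (seed fixed)")
        rng = np.random.default_rng(jitter_seed)
        scale = 1e-9 * max(d.max(), 1.0)
        pts = pts + rng.normal(0.0, scale, size=pts.shape)
        d = squareform(pdist(pts))
    # sparse input: the dense path of minimum_spanning_tree nulls out
    # near-zero edge weights (e.g. jittered duplicates)
    mst = minimum_spanning_tree(csr_matrix(d))
    dist = dijkstra(mst, directed=False, indices=[d.shape[0] - 1])[0][:-1]
    maxd = dist.max()
    return dist / maxd if maxd > 0 else np.zeros(X.shape[0])


def assign_subtrajectories(
    cpc_scores: np.ndarray,
    max_subtrajectories: int = 10,
    membership_tolerance: float = 0.1,
    seed: int = 0,
) -> tuple[list[list[int]], int, np.ndarray]:
    """Probabilistic subtrajectory assignment in the contrasted space.

    A Gaussian-mixture model is fitted to the scores with the number of
    components chosen in [2, max] by the Bayesian information criterion;
    soft memberships are the posterior component probabilities.  Every
    cluster whose posterior lies within ``membership_tolerance`` of a
    subject's top posterior is kept, ordered most- to least-probable, so
    subjects near a branch point genuinely belong to several
    subtrajectories.

    Returns ``(memberships, n_subtrajectories, membership_matrix)``.
    """
    if max_subtrajectories < 2:
        raise ValueError("max_subtrajectories must be at least 2")
    X = np.atleast_2d(np.asarray(cpc_scores, float))
    n = X.shape[0]
    k_max = max(2, min(max_subtrajectories, n - 1))

    best = None
    for k in range(2, k_max + 1):
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             n_init=3, random_state=seed).fit(X)
        bic = gm.bic(X)
        if best is None or bic < best[0]:
            best = (bic, k, gm)
    _, n_clusters, gm = best
    probs = gm.predict_proba(X)

    memberships: list[list[int]] = []
    for i in range(n):
        order = np.argsort(-probs[i], kind="stable")
        top = probs[i, order[0]]
        keep = [int(c) for c in order if probs[i, c] >= top - membership_tolerance]
        memberships.append(keep)
    return memberships, n_clusters, probs


# ---------------------------------------------------------------------------
# (v) feature contributions
# ---------------------------------------------------------------------------

def feature_contributions(model: CPCAModel) -> np.ndarray:
    """Percent contribution of each feature to the retained components.

    ``C_i = 100 * sum_j lambda_j^norm * w_ij^2 / sum_k w_kj^2`` over the
    components whose normalized eigenvalue exceeds the cutoff; with all
    components retained the contributions sum to exactly 100.
    """
    n_cpc = model.n_cpc
    if n_cpc == 0:
        raise ValueError("no component passes the eigenvalue cutoff; lower it")
    W2 = model.loadings[:, :n_cpc] ** 2
    col_sums = W2.sum(axis=0)
    lam = model.normalized_eigenvalues[:n_cpc]
    return 100.0 * (W2 / col_sums) @ lam


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_cti(
    table: FeatureTable,
    keep_fraction: float = 1.0,
    k_neighbors: int = 10,
    adjust: bool | None = None,
    max_components: int | None = None,
    max_subtrajectories: int = 10,
    membership_tolerance: float = 0.1,
    eigenvalue_cutoff: float = 0.025,
    seed: int = 0,
) -> TrajectoryResult:
    """Full contrastive-trajectory pipeline on a labeled feature table.

    Background and target populations come from the table's
    ``background_ids``/``target_ids``; subjects labeled neither are still
    projected, ordered and clustered.  Set ``keep_fraction < 1`` to enable
    feature preselection.
    """
    if not table.background_ids:
        raise ValueError("table must define background_ids")
    work = table
    if adjust is None:
        adjust = table.covariates is not None
    if adjust:
        work = adjust_covariates(work)

    if keep_fraction < 1.0:
        pre_idx = preselect_features(work, keep_fraction, k_neighbors)
    else:
        pre_idx = np.arange(work.n_features)
    X = boxcox_standardize(work.values[:, pre_idx])

    bg_idx = work.index_of(work.background_ids)
    tg_ids = work.target_ids or [s for s in work.subject_ids
                                 if s not in set(work.background_ids)]
    tg_idx = work.index_of(tg_ids)

    model = cpca_decompose(X[tg_idx], X[bg_idx], max_components=max_components,
                           eigenvalue_cutoff=eigenvalue_cutoff, seed=seed)
    scores = model.transform(X)
    pseudotimes = compute_pseudotimes(scores, bg_idx, jitter_seed=seed)
    # equalize component scales before clustering: the progression axis
    # otherwise dominates the distance matrix and subtrajectory branches
    # (which separate along weaker components) become invisible
    sd = scores.std(axis=0)
    scaled = (scores - scores.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    memberships, n_subtraj, _ = assign_subtrajectories(
        scaled, max_subtrajectories, membership_tolerance, seed=seed)
    contributions = feature_contributions(model)
    return TrajectoryResult(
        pseudotimes=pseudotimes, memberships=memberships,
        n_subtrajectories=n_subtraj, contributions=contributions,
        preselected_indices=pre_idx, model=model, scores=scores,
        subject_ids=list(table.subject_ids),
    )


def write_cti_results(outdir, result: TrajectoryResult, name: str = "data") -> None:
    """Write the documented cTI output tables."""
    from pathlib import Path

    from .io import write_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = len(result.subject_ids)
    max_m = max(len(m) for m in result.memberships)
    rows = np.full((n, 2 + max_m), np.nan)
    for i in range(n):
        rows[i, 0] = float(i + 1)
        rows[i, 1] = result.pseudotimes[i]
        for j, c in enumerate(result.memberships[i]):
            rows[i, 2 + j] = c + 1
    write_matrix(outdir / f"cTI_IDs_pseudotimes_pseudopaths_{name}.txt", rows)
    if result.scores is not None:
        write_matrix(outdir / f"cTI_cPCs_{name}.txt", result.scores)
    if result.model is not None:
        write_matrix(outdir / f"cTI_weights_{name}.txt",
                     result.model.loadings[:, :result.model.n_cpc])
    write_matrix(outdir / f"cTI_features_contributions_{name}.txt",
                 result.contributions[None, :])
    if result.preselected_indices is not None:
        write_matrix(outdir / f"cTI_features_preselected_{name}.txt",
                     (result.preselected_indices + 1)[None, :].astype(float))
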