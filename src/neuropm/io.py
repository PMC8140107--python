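"""Input/output, data cleaning and cohort-assembly utilities.

This module owns the file conventions shared by all engines: plain-text
subjects-by-features matrices, region-by-region connectomes, per-subject
regional time series (one file per factor and time point), external-input
schedules, and the aggregation of voxel volumes to parcellation regions.
It also provides the standard cleaning steps (three-sigma outlier flagging,
trimmed-scores imputation) and the bridge that turns a cross-sectional
cohort plus a pseudotime stratification into pseudo-longitudinal series.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "FeatureTable",
    "Connectome",
    "RegionalSeries",
    "read_feature_matrix",
    "write_matrix",
    "read_matrix",
    "read_connectome",
    "write_connectome",
    "load_volume",
    "aggregate_parcellation",
    "detect_outliers_three_sigma",
    "impute_trimmed_scores",
    "build_pseudo_longitudinal",
    "read_input_schedule",
    "read_output_variables",
    "import_esm_dataset",
    "import_mcm_dataset",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Subjects-by-features matrix with identifiers and optional covariates.

    ``background_ids`` name the reference (e.g. healthy) subpopulation and
    ``target_ids`` the population of interest; they must be disjoint subsets
    of ``subject_ids``.
    """

    values: np.ndarray
    subject_ids: list[str]
    feature_names: list[str]
    covariates: np.ndarray | None = None
    covariate_names: list[str] | None = None
    background_ids: list[str] = field(default_factory=list)
    target_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D subjects x features matrix")
        n, p = self.values.shape
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match row count")
        if len(self.feature_names) != p:
            raise ValueError("feature_names length does not match column count")
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject_ids must be unique")
        known = set(self.subject_ids)
        for ids, label in ((self.background_ids, "background"), (self.target_ids, "target")):
            unknown = set(ids) - known
            if unknown:
                raise ValueError(f"{label}_ids not present in subject_ids: {sorted(unknown)}")
        if set(self.background_ids) & set(self.target_ids):
            raise ValueError("background and target populations must be disjoint")
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.ndim == 1:
                self.covariates = self.covariates[:, None]
            if self.covariates.shape[0] != n:
                raise ValueError("covariates row count does not match subjects")
            if self.covariate_names is None:
                self.covariate_names = [f"cov{i + 1}" for i in range(self.covariates.shape[1])]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.subject_ids)}
        return np.array([lookup[s] for s in ids], dtype=int)


@dataclass
class Connectome:
    """Weighted region-by-region connectivity matrix.

    Entry ``(i, j)`` is the connection from region *j* into region *i*
    (column = source, row = sink); a symmetric matrix is unaffected by this
    convention.  ``region_labels`` carry the parcellation label value of each
    row/column, in ascending-label order.
    """

    weights: np.ndarray
    region_labels: list[int] | None = None
    name: str = "anatomical"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("connectome must be a square matrix")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("connectome contains non-finite entries")
        if np.any(self.weights < 0):
            raise ValueError("connectome weights must be nonnegative")
        if self.region_labels is None:
            self.region_labels = list(range(1, self.weights.shape[0] + 1))
        elif len(self.region_labels) != self.weights.shape[0]:
            raise ValueError("region_labels length does not match matrix size")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def row_normalized(self) -> "Connectome":
        """Divide every row by its sum (rows with zero sum are left as-is)."""
        w = self.weights.copy()
        sums = w.sum(axis=1, keepdims=True)
        nz = sums[:, 0] > 0
        w[nz] /= sums[nz]
        return Connectome(w, list(self.region_labels), self.name)


@dataclass
class RegionalSeries:
    """Per-subject regional values over acquisition times and modalities.

    ``values`` has shape [N_rois, N_modalities, N_times]; ``mask`` is True
    where an observation is present.  Times share one caller-defined unit
    (years for real studies, dimensionless pseudotime in [0, 1] for
    pseudo-longitudinal cohorts).
    """

    subject_id: str
    modalities: list[str]
    times: np.ndarray
    values: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:  # single modality convenience
            self.values = self.values[:, None, :]
        if self.values.ndim != 3:
            raise ValueError("values must be [N_rois x N_modalities x N_times]")
        if self.values.shape[1] != len(self.modalities):
            raise ValueError("modalities length does not match values")
        if self.values.shape[2] != self.times.size:
            raise ValueError("times length does not match values")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape does not match values")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("values must be finite where mask is True")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.times.size


# ---------------------------------------------------------------------------
# Plain-text matrices
# ---------------------------------------------------------------------------

_DELIMITERS = ("\t", ",", None)  # None = any whitespace; tried in this order


def _parse_text_matrix(path: str | Path) -> np.ndarray:
    """Parse a rectangular numeric table, auto-detecting the delimiter."""
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    last_err: Exception | None = None
    for delim in _DELIMITERS:
        rows = [ln.split(delim) for ln in lines]
        rows = [[c for c in r if c.strip() != ""] for r in rows]
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            last_err = ValueError(
                f"{path}: ragged rows (widths {sorted(widths)}) with delimiter {delim!r}"
            )
            continue
        try:
            return np.array([[float(c) for c in r] for r in rows], dtype=float)
        except ValueError:
            # wrong dialect (e.g. comma file split on tabs) or a genuinely
            # non-numeric cell; keep the located error and try the next
            for i, r in enumerate(rows):
                for j, c in enumerate(r):
                    try:
                        float(c)
                    except ValueError:
                        last_err = ValueError(
                            f"{path}: non-numeric value {c!r} at row {i + 1}, "
                            f"column {j + 1}"
                        )
                        break
                else:
                    continue
                break
            continue
    raise last_err if last_err is not None else ValueError(f"{path}: unparseable")


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a plain-text numeric matrix (whitespace-, tab- or comma-delimited)."""
    return _parse_text_matrix(path)


def write_matrix(path: str | Path, matrix: np.ndarray, fmt: str = "%.6g") -> None:
    np.savetxt(path, np.atleast_2d(np.asarray(matrix, dtype=float)), fmt=fmt, delimiter="\t")


def read_feature_matrix(path: str | Path, id_policy: str = "row-number") -> FeatureTable:
    """Read a subjects-by-features table.

    With ``id_policy='row-number'`` the subject ID is the 1-based row
    position; with ``'first-column'`` the first column carries the IDs.
    """
    if id_policy not in ("row-number", "first-column"):
        raise ValueError(f"unknown id_policy {id_policy!r}")
    raw = _parse_text_matrix(path)
    if id_policy == "first-column":
        ids = [("%g" % v) for v in raw[:, 0]]
        values = raw[:, 1:]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{path}: duplicate IDs in first column")
    else:
        ids = [str(i + 1) for i in range(raw.shape[0])]
        values = raw
    names = [f"f{j + 1}" for j in range(values.shape[1])]
    return FeatureTable(values=values, subject_ids=ids, feature_names=names)


def read_connectome(path: str | Path, n_expected: int | None = None,
                    name: str = "anatomical") -> Connectome:
    """Read a square nonnegative connectivity matrix from plain text."""
    w = _parse_text_matrix(path)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"{path}: connectome is {w.shape[0]}x{w.shape[1]}, expected square")
    if n_expected is not None and w.shape[0] != n_expected:
        raise ValueError(f"{path}: connectome has {w.shape[0]} regions, expected {n_expected}")
    if not np.all(np.isfinite(w)):
        raise ValueError(f"{path}: connectome contains NaN/inf entries")
    if np.any(w < 0):
        raise ValueError(f"{path}: negative connectome weight")
    return Connectome(w, name=name)


def write_connectome(path: str | Path, connectome: Connectome) -> None:
    write_matrix(path, connectome.weights)


# ---------------------------------------------------------------------------
# Volumes and parcellation aggregation
# ---------------------------------------------------------------------------

def load_volume(source) -> np.ndarray:
    """Return a 3-D array from an array-like or a NIfTI/MINC file path."""
    if isinstance(source, (str, Path)):
        import nibabel as nib

        return np.asanyarray(nib.load(str(source)).dataobj, dtype=float)
    return np.asarray(source, dtype=float)


def aggregate_parcellation(
    image,
    parcellation,
    reference_labels: Sequence[int] | None = None,
    probabilistic: bool = False,
    reverse_scale: bool = False,
    keep_reference: bool = False,
) -> tuple[np.ndarray, list[int]]:
    """Aggregate a voxel volume to per-region mean values.

    Regions are the positive labels of ``parcellation``, ordered by ascending
    label value (the contract shared with connectome row order).  When
    ``reference_labels`` are given, regional means are divided by the mean
    voxel value over the reference regions (SUVr-style standardization) and
    the reference regions are dropped unless ``keep_reference``.  With
    ``probabilistic`` the voxel values are first converted to probabilities
    via the empirical CDF of the per-reference-region maxima.  With
    ``reverse_scale`` the output vector is reflected, ``x -> max + min - x``,
    for modalities whose numeric scale runs opposite to pathology severity.

    Returns ``(regional_values, labels)``.
    """
    img = load_volume(image)
    parc = np.asarray(load_volume(parcellation))
    if img.shape != parc.shape:
        raise ValueError(f"image grid {img.shape} does not match parcellation {parc.shape}")
    parc = np.round(parc).astype(int)
    labels = sorted(int(v) for v in np.unique(parc) if v > 0)
    if not labels:
        raise ValueError("parcellation defines no positive labels")

    if probabilistic:
        if not reference_labels:
            raise ValueError("probabilistic standardization requires reference_labels")
        maxima = np.array([img[parc == lab].max() for lab in reference_labels
                           if np.any(parc == lab)])
        if maxima.size == 0:
            raise ValueError("reference labels absent from parcellation")
        sorted_max = np.sort(maxima)
        img = np.searchsorted(sorted_max, img, side="right") / sorted_max.size

    values = np.full(len(labels), np.nan)
    for k, lab in enumerate(labels):
        sel = parc == lab
        if not np.any(sel):  # pragma: no cover - labels come from unique()
            warnings.warn(f"region label {lab} has no voxels; value set to missing")
            continue
        values[k] = float(img[sel].mean())

    if reference_labels is not None and not probabilistic:
        ref_sel = np.isin(parc, list(reference_labels))
        if not np.any(ref_sel):
            raise ValueError("reference labels absent from parcellation")
        ref_mean = float(img[ref_sel].mean())
        if ref_mean == 0:
            raise ValueError("reference region mean is zero; cannot standardize")
        values = values / ref_mean

    if reference_labels is not None and not keep_reference:
        keep = [k for k, lab in enumerate(labels) if lab not in set(reference_labels)]
        values = values[keep]
        labels = [labels[k] for k in keep]

    if reverse_scale:
        finite = values[np.isfinite(values)]
        if finite.size:
            values = finite.max() + finite.min() - values
    return values, labels


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------

def detect_outliers_three_sigma(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Flag entries deviating from their group mean by more than 3 SD.

    Plain sample statistics (including the tested entry) are taken along
    ``axis``; groups with zero variance flag nothing.  NaNs are ignored and
    never flagged.
    """
    x = np.asarray(values, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(x, axis=axis, keepdims=True)
        sd = np.nanstd(x, axis=axis, keepdims=True, ddof=0)
    mask = np.abs(x - mean) > 3.0 * sd
    mask &= sd > 0
    mask &= np.isfinite(x)
    return mask


def impute_trimmed_scores(
    values: np.ndarray,
    n_components: int = 2,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> np.ndarray:
    """Complete missing (NaN) cells by iterative PCA-model regression.

    Trimmed-scores regression: missing cells start at their column mean; the
    data are then alternately projected on the leading ``n_components``
    principal components and the missing cells replaced by the model
    reconstruction, until the largest imputed-cell change falls below
    ``tol``.  Deterministic given its inputs, and a projection: re-running it
    on its own output is a no-op.
    """
    X = np.asarray(values, dtype=float).copy()
    if X.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    missing = ~np.isfinite(X)
    if not missing.any():
        return X
    frac = missing.mean(axis=0)
    if np.any(frac >= 1.0):
        raise ValueError("column(s) entirely missing; cannot impute")
    if np.any(frac >= 0.5):
        bad = np.nonzero(frac >= 0.5)[0]
        raise ValueError(f"column(s) {bad.tolist()} are >=50% missing; cannot impute")
    n_components = int(min(n_components, min(X.shape)))

    col_mean = np.nanmean(X, axis=0)
    X[missing] = np.take(col_mean, np.nonzero(missing)[1])
    for _ in range(max_iter):
        mu = X.mean(axis=0)
        Xc = X - mu
        # leading principal axes of the completed data
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        P = Vt[:n_components].T
        recon = (Xc @ P) @ P.T + mu
        delta = np.max(np.abs(X[missing] - recon[missing]))
        X[missing] = recon[missing]
        if delta < tol:
            break
    else:
        warnings.warn("trimmed-scores imputation did not converge; returning last iterate")
    return X


# ---------------------------------------------------------------------------
# Pseudo-longitudinal bridge
# ---------------------------------------------------------------------------

def build_pseudo_longitudinal(
    cohort: Sequence[RegionalSeries],
    pseudotimes: Mapping[str, float],
    memberships: Mapping[str, Sequence[int]],
) -> dict[int, RegionalSeries]:
    """Order baseline observations along pseudotime, per subtrajectory.

    Every subject must contribute exactly one baseline observation; its
    pseudotime in [0, 1] becomes the "acquisition time" of the pseudo-
    longitudinal group series.  Subjects belonging to several subtrajectories
    appear in each.  Ties in pseudotime are broken by lexicographic subject
    ID so the output is deterministic.
    """
    by_subtraj: dict[int, list[tuple[float, str, RegionalSeries]]] = {}
    for series in cohort:
        if series.n_times != 1:
            raise ValueError(
                f"subject {series.subject_id}: expected a single baseline observation"
            )
        sid = series.subject_id
        if sid not in pseudotimes:
            warnings.warn(f"subject {sid} has no pseudotime; excluded")
            continue
        pt = float(pseudotimes[sid])
        if not 0.0 <= pt <= 1.0:
            raise ValueError(f"subject {sid}: pseudotime {pt} outside [0, 1]")
        for k in memberships.get(sid, ()):
            by_subtraj.setdefault(int(k), []).append((pt, sid, series))

    out: dict[int, RegionalSeries] = {}
    for k, entries in sorted(by_subtraj.items()):
        entries.sort(key=lambda e: (e[0], e[1]))
        times = np.array([e[0] for e in entries])
        # strictly-increasing times are required downstream: spread exact ties
        # by the smallest representable nudge
        for i in range(1, times.size):
            if times[i] <= times[i - 1]:
                times[i] = np.nextafter(times[i - 1], np.inf)
        values = np.concatenate([e[2].values for e in entries], axis=2)
        out[k] = RegionalSeries(
            subject_id=f"Subgroup_{k}",
            modalities=list(entries[0][2].modalities),
            times=times,
            values=values,
        )
    return out


# ---------------------------------------------------------------------------
# Schedules and auxiliary tables
# ---------------------------------------------------------------------------

def read_input_schedule(path: str | Path) -> list[dict]:
    """Parse an external-input schedule file.

    Each row reads ``start stop intensity target_region [target_region ...]``
    with 1-based region indices.  Returns a list of dicts with keys
    ``start``, ``stop``, ``intensity``, ``regions`` (0-based).
    """
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    schedule = []
    for r, ln in enumerate(lines):
        try:
            row = np.array([float(c) for c in ln.replace(",", " ").split()])
        except ValueError:
            raise ValueError(f"input schedule row {r + 1}: non-numeric value") from None
        if row.size < 4:
            raise ValueError(f"input schedule row {r + 1}: need start stop intensity regions...")
        start, stop, intensity = row[0], row[1], row[2]
        if stop < start:
            raise ValueError(f"input schedule row {r + 1}: stop {stop} < start {start}")
        regions = [int(v) - 1 for v in row[3:]]
        if any(v < 0 for v in regions):
            raise ValueError(f"input schedule row {r + 1}: region indices are 1-based")
        schedule.append({"start": float(start), "stop": float(stop),
                         "intensity": float(intensity), "regions": regions})
    return schedule


def read_output_variables(path: str | Path) -> np.ndarray:
    """Read the cognitive/output variable table (rows = time points)."""
    return np.atleast_2d(_parse_text_matrix(path))


# ---------------------------------------------------------------------------
# Folder walkers ("import" commands)
# ---------------------------------------------------------------------------

_FACTOR_RE = re.compile(r"^factor_(\d+)_t(\d+)\.(\w+)$")
_CONNECTOME_RE = re.compile(r"^connectome(\d+)_t(\d+)\.txt$")
_PARCELLATION_RE = re.compile(r"^GM_parcellation_t(\d+)\.(\w+)$")

_VOLUME_EXTS = {"nii", "gz", "mnc"}


def _scan_subject_dir(folder: Path) -> dict:
    factors: dict[tuple[int, int], Path] = {}
    connectomes: dict[tuple[int, int], Path] = {}
    parcellations: dict[int, Path] = {}
    for f in sorted(folder.iterdir()):
        if not f.is_file():
            continue
        name = f.name.replace(".nii.gz", ".nii")
        m = _FACTOR_RE.match(name)
        if m:
            factors[(int(m.group(1)), int(m.group(2)))] = f
            continue
        m = _CONNECTOME_RE.match(f.name)
        if m:
            connectomes[(int(m.group(1)), int(m.group(2)))] = f
            continue
        m = _PARCELLATION_RE.match(name)
        if m:
            parcellations[int(m.group(1))] = f
    return {"factors": factors, "connectomes": connectomes, "parcellations": parcellations}


def _read_regional_file(path: Path, parcellation: Path | None) -> np.ndarray:
    if path.suffix.lstrip(".").lower() in _VOLUME_EXTS:
        if parcellation is None:
            raise ValueError(f"{path}: volume input requires a parcellation file")
        values, _ = aggregate_parcellation(path, parcellation)
        return values
    vec = _parse_text_matrix(path)
    return vec.reshape(-1)


def _assemble_series(subject_id: str, scan: dict, root_scan: dict) -> RegionalSeries | None:
    factors = scan["factors"] or root_scan["factors"]
    if not factors:
        return None
    factor_ids = sorted({k for k, _ in factors})
    time_ids = sorted({j for _, j in factors})
    parcellations = scan["parcellations"] or root_scan["parcellations"]
    n_rois = None
    values = None
    for fi, k in enumerate(factor_ids):
        for ti, j in enumerate(time_ids):
            path = factors.get((k, j))
            if path is None:
                continue
            vec = _read_regional_file(path, parcellations.get(j))
            if n_rois is None:
                n_rois = vec.size
                values = np.full((n_rois, len(factor_ids), len(time_ids)), np.nan)
            if vec.size != n_rois:
                raise ValueError(
                    f"{path}: {vec.size} regions, expected {n_rois} (subject {subject_id})"
                )
            values[:, fi, ti] = vec
    return RegionalSeries(
        subject_id=subject_id,
        modalities=[f"factor_{k}" for k in factor_ids],
        times=np.array(time_ids, dtype=float),
        values=values,
    )


def _import_dataset(root: str | Path) -> dict:
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"{root} is not a directory")
    root_scan = _scan_subject_dir(root)
    subjects: dict[str, RegionalSeries] = {}
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        scan = _scan_subject_dir(sub)
        series = _assemble_series(sub.name, scan, root_scan)
        if series is not None:
            subjects[sub.name] = series
    if not subjects:
        series = _assemble_series("group", root_scan, root_scan)
        if series is not None:
            subjects["group"] = series
    conn_paths = root_scan["connectomes"]
    connectomes = {k: read_connectome(p, name=f"connectome{k[0]}")
                   for k, p in sorted(conn_paths.items())}
    return {"subjects": subjects, "connectomes": connectomes}


def import_esm_dataset(root: str | Path) -> dict:
    """Walk an ESM input folder (factor_<k>_t<j> files, connectome<k>_t<j>.txt)."""
    return _import_dataset(root)


def import_mcm_dataset(root: str | Path) -> dict:
    """Walk an MCM input folder; also picks up input/output variable tables."""
    out = _import_dataset(root)
    root = Path(root)
    sched = root / "input_variable.txt"
    out["input_schedule"] = read_input_schedule(sched) if sched.exists() else None
    outv = root / "outputs_variables.txt"
    out["output_variables"] = read_output_variables(outv) if outv.exists() else None
    return out
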