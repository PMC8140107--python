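# Methods

This package implements four analytical engines for modelling
neurodegenerative disease progression from cross-sectional and longitudinal
multimodal data, together with the file-format plumbing and synthetic-data
generators needed to exercise them end to end without any external dataset.

## Contrastive trajectory inference (cTI)

**Model.** Cross-sectional subjects are ordered along a latent progression
axis by contrasting a target population (patients) against a background
population (healthy references). The pipeline is: (i) optional covariate
adjustment, (ii) optional feature preselection, (iii) Box-Cox
standardization, (iv) contrastive PCA with automatic contrast-strength
selection, (v) pseudotimes, subtrajectories, and per-feature contributions.

*Covariate adjustment* residualizes each feature on a robust (IRLS with
Huber weights, via statsmodels RLM) linear model containing an intercept,
main effects and all pairwise interactions between distinct covariates.
Covariates with fewer than 7 unique values are treated as categorical and
expanded to one indicator per level; aliased design columns are dropped.
Residuals are re-centered to each feature's original mean.

*Preselection* scores each feature as sample variance minus neighborhood
variance, where the neighborhood variance is the mean squared difference
between a subject's value and the values of its k = 10 nearest neighbors in
the full feature space. Features that vary smoothly along a latent ordering
score positive; unstructured features score at or below zero; constant
features are forced to the bottom of the ranking.

*Contrastive PCA.* For each of 100 log-spaced contrast strengths
α ∈ [1e-2, 1e2] the leading eigenvectors of `C_target − α·C_background`
define a candidate subspace. Candidates are clustered into 4 representative
subspaces by spectral clustering of their principal-angle affinity. The
representative is selected by **spectral concentration**: the largest
normalized eigenvalue `λ₁^norm = (λ₁−min λ)/Σ(λ−min λ)` of its contrast.
A genuine contrast packs target-enriched variance into few directions
(λ₁^norm ≈ 0.4–0.5 on the synthetic cohorts) while a contrast dominated by
background sampling noise spreads it thin (≈ 0.04). We found
occupancy-style clustering-tendency statistics (Hopkins, silhouette)
unable to make this distinction — a Gaussian blob and a heavy-tailed noise
cloud both look "clustered" against a uniform reference box — so the
concentration criterion is this package's design choice for the automatic
subspace selection. `hopkins_statistic` remains available as a diagnostic.

*Pseudotimes* are minimum-spanning-tree path lengths from each subject to a
virtual node at the background centroid, computed on the raw contrasted
scores (the progression axis should dominate there) and normalized by the
population maximum into [0, 1]. Exactly duplicated coordinates receive an
infinitesimal deterministic jitter (seed 0) before tree construction.

*Subtrajectories* are identified by a full-covariance Gaussian mixture on
the variance-equalized retained components, with the number of components
chosen in [2, max] by BIC. Two design choices matter here and are this
package's own: (a) component scales are equalized before clustering because
the progression axis otherwise dominates every pairwise distance and
branch structure (which separates along weaker components) is invisible;
(b) a mixture model replaces spectral clustering of the distance matrix
because on branched trajectory geometries the graph Laplacian's 2nd/3rd
eigenvalues are nearly degenerate, making the spectral embedding — and the
resulting labels — numerically irreproducible across linear-algebra
backends, whereas mixture posteriors are stable and directly provide the
soft multi-membership probabilities (a subject is assigned to every
subtrajectory whose posterior is within `membership_tolerance`, default
0.1, of its maximum).

*Contributions.* Feature i's contribution is
`C_i = 100 Σ_j λ_j^norm ω_ij² / Σ_k ω_kj²` over the components whose
normalized eigenvalue exceeds 0.025 (overridable); with every component
retained the contributions sum to exactly 100.

## Epidemic spreading model (ESM)

**Model.** Regional agent levels follow
`dS_i/dt = (1 − S_i/maxS) ε_i − δ_i S_i` with incoming pressure
`ε_i = Σ_{j≠i} Pa_{j→i} β_j^ext S_j + Pa_{i→i} β_i^int S_i`, where the
extrinsic/intrinsic split `β^ext = g·β`, `β^int = (1−g)·β` is governed by
the Gini coefficient g of the instantaneous regional distribution.
Rates are constant (`β_o`, `δ_o`) or saturating
(`β_i = 1 − exp(−β_o S_i/maxS)`, `δ_i = exp(−δ_o S_i/maxS)`). g is
recomputed from the current state at every derivative evaluation.
Integration uses adaptive RK45 (rtol 1e-6, atol 1e-9) with post-hoc
clipping to [0, maxS]; overshoot beyond tolerance raises.

The connectome is used as given (row normalization optional). A zero
diagonal would annul the intrinsic term identically, so absent
self-connections default to `Pa_{i→i} = 1`.

**Fitting** minimizes the squared misfit over all regions and time points
(≥ 3 required) by bounded trust-region least squares from Latin-hypercube
multistarts (default 32; deterministic seed) over `(β_o, δ_o[, t0])` with
`β, δ ∈ [0, 10]` and the onset bounded by `[min_onset, t_first]`. For each
start the onset state is back-projected by integrating the model backwards
from the first observation; regions whose back-projected level exceeds the
non-epicenter ceiling (default 5% of maxS) become free S0 entries — at most
`max_epicenters`, by rank — and all others are clamped at the ceiling.
Candidate epicenters are reported ranked by fitted onset level. `maxS` is
the population maximum and should be supplied when a single subject's data
do not approach it; effective production/clearance rates are the
state-dependent rates averaged over a 201-point uniform grid on [0, maxS].

## Multifactorial causal model (MCM)

**Model.** A linear dynamical system `dS/dt = A S + B u`, `Cog = β·S` over
factor-major states of `N_rois × N_f` alteration levels (deviations from a
control-mean or first-evaluation reference). A is assembled from:
`local_interactions` (N_f × N_f, shared across regions), per-factor
`spreading_weights` over the connectome(s) with zeroed diagonal (so
self-effects live only in the local couplings), `network_fractions` mixing
two connectomes, and `input_effects` scaling a piecewise-constant external
input. A is time-invariant within a fit. Simulation is exact matrix-
exponential propagation between input breakpoints (augmented-matrix form
for the forced term). Cognitive weights β are estimated a priori at the
population level by OLS, or GCV-ridge when under-determined.

**Fitting** (≥ 3 time points). The default *spline* route is gradient
matching in integrated (collocation) form: the exactly-observed increments
`S(t_{k+1}) − S(t_k)` are regressed on the interpolating-spline integrals
`∫ Ŝ dt` over each inter-observation interval, with the bilinear pair
(spreading weight × network fraction) reparametrized as two nonnegative
per-connectome weights so the regression is linear, and a Tikhonov penalty
of 1e-4 (relative to the Gram-matrix trace) per target factor. The
integrated form was chosen over derivative matching because with ~6 time
points the spline-derivative bias alone contributes ~5% parameter error,
versus ~0.5% for the integral form. Smoothing splines (penalty chosen per
curve by GCV over a 25-point λ grid; series shorter than 5 points fall
back to interpolation) provide the dense state estimates. The *multistart*
route minimizes the simulated-vs-observed misfit by bounded least squares
from seeded random starts plus the spline solution as a warm start
(defaults: 32 starts × 3 rounds).

**Effective metrics.** For each target factor the absolute modeled
contributions — each source factor's direct effect, connectome spreading,
external input — are accumulated over regions and observed times and
expressed as percentages of their total, so per target they sum to 100.
"Incoming" is the off-diagonal column sum (≤ 100 by construction);
"outgoing" aggregates a source factor's cross-factor numerators over the
same per-target denominators, keeping it in [0, 100]. Weighting direct
effects by state magnitude (rather than raw coefficients) is an
interpretation; the alternative changes only the relative scale of strong
vs weak factors.

## Intervention fingerprints (pTIF)

For every non-empty factor subset up to `max_combination` (canonical order:
subset size, then lexicographic; 63 subsets for 6 factors) the input matrix
B selects all regions of the chosen factors. The finite-horizon
controllability Gramian `W(t0,tf) = ∫ e^{A(t0−t)} B Bᵀ e^{Aᵀ(t0−t)} dt` is
computed by 64-node Gauss–Legendre quadrature (symmetrized; a runtime
self-check doubles the node count for the first subset and warns if J moves
by more than 1e-6 relative). The minimum-energy control is applied in the
t0 frame, `u(t) = −Bᵀ e^{Aᵀ(t0−t)} W⁻¹ e^{A(t0−tf)} D` with
`D = e^{A(tf−t0)} S_start − S_desired`, which is the standard controller
written against this Gramian convention; ill-conditioned W falls back to an
eigenvalue-truncated pseudo-inverse (relative cutoff 1e-10) and
uncontrollable target components trigger a warning with a least-squares
control. Every solution is verified by independently integrating
`dS/dt = AS + Bu(t)` (RK45, rtol 1e-9) and reporting the relative terminal
error. Desired-state rules: `stabilize` (hold the current alteration
pattern), `percent:p` (scale the whole alteration vector to p%), and
`control-mean` (zero in alteration coordinates). The output-control
strategy targets the cognitive score through the output Gramian `φWφᵀ`
with `φ = β e^{A(tf−t0)}`. Energies `J = ∫ uᵀu dt` use the same quadrature
rule; regional energies are the per-controlled-node integrals and sum to J.

## Synthetic data

*Z-score subtype cohorts.* One subtype is a control group (stage compressed
to [0, 0.05], so background subjects carry realistic jitter); each diseased
subtype has its own random monotone ordering of z-score events (levels
1, 2, 3 per informative biomarker; a uniformly random permutation of all
events with each biomarker's levels sorted). A biomarker follows the
piecewise-linear trajectory through its event positions and continues
rising to z_max = 5 at stage 1, as in the linear z-score event-model
family — the continuation matters: with a hard plateau at the last event
the diseased subtypes reconverge at late stage and subtype structure is
unrecoverable in principle. Informative biomarkers add Gaussian noise
(SD 1 by default); the noise biomarkers are standard normal. Defaults
follow the reference simulation design: 3 subtypes, 500 subjects,
50 informative + 50 noise features, uniform stages.

*Connectomes* are connected Erdős–Rényi graphs with lognormal weights and
zero diagonal (resampled until connected).

*ESM/MCM cohorts* simulate the forward models at known parameters and add
Gaussian observation noise; per-subject streams are spawned from
(seed, subject index) so regeneration is order-independent. The ESM
recovery study uses a 10-node connectome scaled to mean row-sum 3 with
β_o = 4, δ_o = 5, one epicenter seeded at 0.3, six observations over
t ∈ [1, 6] and noise SD = 2% of maxS — a regime where the epidemic
genuinely propagates (mean burden rising from ≈ 0.06 to ≈ 0.5); in
clearance-dominated regimes the observations carry almost no information
about the rates. The MCM recovery study uses 2 factors × 8 regions with a
stable coupling matrix and 6 noiseless time points on t ∈ [0, 5].

**What the generators do not emulate:** scanner physics, spatial noise
correlations, site/batch effects, missing visits, diagnosis-dependent
sampling, or model mismatch (the fitted model class always contains the
generating process). Passing recovery tests therefore demonstrates
correctness of the estimators under the stated models, not robustness of
the models to real data.

## Numerical choices and degenerate inputs

- Matrix text I/O at `%.6g`; delimiter auto-detection tries tab, comma,
  then whitespace, keeping the first rectangular numeric parse.
- Eigenvector sign convention: each loading column is oriented so its
  largest-magnitude entry is positive.
- Three-sigma outliers use plain sample statistics including the tested
  entry; a zero-variance group flags nothing. (Note a single gross outlier
  among very few observations inflates the SD enough to escape the rule —
  an intrinsic property of the plain three-sigma formula.)
- Trimmed-scores imputation: column-mean initialization, alternating
  projection on the leading principal components, tol 1e-6 on the largest
  imputed-cell change, at most 2000 iterations (convergence is linear and
  can be slow near rank deficiency); columns ≥ 50% missing are rejected.
- Pseudo-longitudinal series break pseudotime ties lexicographically by
  subject ID and nudge exact ties by one ULP so times stay strictly
  increasing.
- MST construction feeds an explicitly sparse matrix to scipy's
  `minimum_spanning_tree`; the dense code path silently nulls near-zero
  edge weights (such as jittered duplicates).
- All stochastic components (multistarts, mixtures, jitter, generators)
  take explicit seeds and default to 0; identical inputs and seeds give
  identical outputs.

## Problem sizes

The test suite runs every engine at the scales stated above: cTI at
500 × 100 (seconds), ESM recovery over 20 subjects on 10 regions
(a few minutes; the dominant cost is the ODE solves inside multistart
least squares), MCM at 2 × 8 × 6 (seconds to ~1 minute including the
32 × 3 multistart), and control round-trips at state dimension 12.

## Known limitations

- The cTI subspace selection assumes the informative contrast concentrates
  variance; adversarial backgrounds with genuinely flat target-specific
  spectra would defeat it.
- ESM onset-time and epicenter estimation rely on backward integration,
  which loses accuracy over long pre-observation horizons.
- MCM assumes region-homogeneous factor couplings and a time-invariant
  operator; regional heterogeneity enters only through states and
  connectomes.
- pTIF energies are for the fitted linear model; they quantify model-based
  controllability, not clinical feasibility.
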