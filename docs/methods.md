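# Methods

## Morphological connectivity

The quantity at the core of the package is a per-subject similarity between
the distributions of gray-matter (GM) density values in two brain regions.
The inputs are assumed to be VBM-style GM probability/density volumes —
segmentation, spatial normalization, modulation and smoothing are upstream of
this package and are not reimplemented. An optional Gaussian smoothing
operation (FWHM specified in mm, converted per axis to
`sigma = fwhm / (2*sqrt(2*ln 2)) / voxel_size` voxels) is provided for
completeness and for adding spatial correlation to synthetic volumes.

**Regional sampling.** For each ROI of a shared-grid integer parcellation,
the sample is the multiset of voxel values where the label matches, filtered
by `value > inclusion_threshold` (default 0). The default excludes
zero-density voxels: a voxel with no gray matter carries no morphological
signal, and including large numbers of exact zeros would put a spurious atom
at the boundary of the density estimate. The threshold is configurable, and
an optional boolean mask (e.g. a group GM mask) can further restrict
sampling. Values above 1, which modulation can produce, are kept and logged
rather than clipped; the renormalization step below absorbs kernel mass
outside [0, 1]. An ROI left empty by filtering, or one with zero variance,
is an error naming the ROI — at ~10^2–10^4 voxels per region these indicate
broken inputs, and silently skipping or patching them would corrupt the
downstream scan.

**Density estimation.** The regional probability density is a Gaussian KDE
with Scott's-rule bandwidth `h = n^(-1/5) * sd` (univariate Scott factor
times the sample standard deviation, ddof = 1 — the same bandwidth
`scipy.stats.gaussian_kde` uses by default; a test asserts the equivalence).
The kernel sum is evaluated directly on a uniform grid of `G = 256` points
spanning [0, 1] — the fixed GM intensity boundary — then floored at
`eps = 1e-10` and renormalized to unit trapezoidal integral. The floor makes
every subsequent KL term finite where an empirical density would otherwise
be numerically zero; it is the standard regularization for divergences of
empirical KDEs. No boundary correction is applied at 0 or 1: the boundary is
honored by evaluating on [0, 1] and renormalizing, not by truncating or
reflecting kernels. `G` and `eps` are configurable (`MCParams`); doubling
`G` from 256 to 512 moves MC values by less than 0.01 on smooth regional
densities (tested), so the default grid is not a binding approximation.

**Similarity.** For two densities on the shared grid the symmetrized
divergence is `KLsym = sum p_i ln(p_i/q_i) dx + sum q_i ln(q_i/p_i) dx`, and

```
MC = exp(-KLsym)  in (0, 1].
```

The exponential map is a design choice: the defining constraints are only
that the similarity lives in (0, 1] with 1 iff the two distributions
coincide, and `exp(-KLsym)` is the simplest strictly decreasing map
satisfying them. The mapping is pluggable (`mc_from_kl`, with `1/(1+KLsym)`
as a built-in alternative) so the choice can be probed. Against discretized
Gaussians, where the symmetric KL has the closed form
`(mu1-mu2)^2/sigma^2 (+ variance terms)`, the discrete computation agrees
within a fraction of a percent at `G = 2048`.

**Profiles.** A parcellation designates one seed ROI per hemisphere; MC is
computed between the seed and each ipsilateral target ROI (contralateral
pairs are not computed — interhemispheric structural connections are sparse
and mostly homotopic, so the scan families are per-hemisphere). A full
ROI-by-ROI matrix mode exists for exploratory use.

## Brain–behavior statistics

**Partial correlation.** Both variables are residualized on an intercept
plus the covariate matrix by least squares; r is the Pearson correlation of
the residuals; the two-sided p-value uses `t = r*sqrt((n-2-k)/(1-r^2))` with
k covariates. This equals the precision-matrix (inverse correlation)
definition to 1e-10 (tested against that oracle and against pingouin).
Covariate coding is irrelevant by affine invariance (asserted for the 0/1
sex code).

**Fisher-z intervals.** `z = atanh(r)`, `se_z = 1/sqrt(n-3)`, bounds
`tanh(z ± z_crit*se_z)`. n is the *total* subject count, not n minus the
number of partialled covariates — this convention (that of the classic
psychometric CIr interval) reproduces published-style intervals for n = 24
at printed precision, which the n−k convention does not. The quantity
reported as the correlation's standard error is `se_z`, the standard error
on the z scale. Published reports sometimes print per-correlation "SE"
values that match neither `se_z` nor `sqrt((1-r^2)/(n-2))`; since the
intended estimand there is unclear, this package reports `se_z` only and
does not attempt to reproduce such values.

**Spearman.** Primary output is the partial Spearman: rank-transform x and y
(average ranks on ties), then run the partial-correlation machinery with the
covariates unranked. Because MC is a bounded, strongly nonlinear function of
any latent trait, rank correlations can legitimately exceed the Pearson r.

**FDR.** Benjamini–Hochberg step-up, implemented via
`statsmodels.multipletests` behind the module surface and verified against a
brute-force enumeration of the step-up definition. The default family is the
set of ipsilateral connections within one hemisphere, applied per
hemisphere, because the scan is run and interpreted hemisphere by
hemisphere; a pooled two-hemisphere family is available
(`fdr_scope="pooled"`).

**Mediation.** Single mediator, linear OLS on standardized
covariate-residualized variables: a from M~X; b and c′ from Y~X+M; c from
Y~X; indirect effect ab. With identical covariate sets the identity
c = c′ + ab holds to numerical precision on every input (tested at 1e-10).
The primary uncertainty statement is a percentile bootstrap CI over subjects
(rows resampled with replacement, covariates included, the whole procedure
repeated; default 5000 draws, seeded), which is robust at n ≈ 24 where
normal-theory indirect-effect tests are not; a Sobel test is emitted as
secondary output. Bootstrap resamples with a constant column are redrawn and
counted. "Full mediation" is flagged when c is significant, c′ is not, and
the bootstrap CI excludes zero. In the pipeline the mediation is run with
X = the total score, M = each subscale, Y = the connection's MC, asking
whether a single facet carries the total-score association.

## The synthetic cohort generator

The generator exists to give every downstream stage a ground truth; it
emulates the *statistical* shape of a small VBM study, not anatomy.

- **ROI intensity distributions** are Beta(α, β) on [0, 1] — support equal
  to the estimator's fixed boundary. Base (α, β) are drawn once per cohort
  per ROI (α, β ~ U[2, 8]; for the seed, α ~ U[2, 4], β ~ U[5, 8], making it
  deliberately asymmetric) and perturbed per subject with N(0, 0.2) jitter,
  which creates between-subject MC variability everywhere.
- **Planted coupling.** One right-hemisphere target interpolates its (α, β)
  between the subject's seed parameters (weight w) and the seed's mirrored
  base parameters (β, α) ("maximally distinct"; far because the seed is
  asymmetric), with `w = sigmoid(coupling_strength * u_i)` and latent trait
  u_i ~ N(0, 1). MC, a distribution similarity, is therefore monotone in the
  trait by construction, and the sign of corr(MC, trait) equals the sign of
  `coupling_strength`. At coupling 0 the weight is constant 0.5 and the pair
  is null. The left hemisphere never carries coupling — a built-in negative
  control.
- **Behavior.** Subscale k is `loading_k * u + N(0, noise_sd)`, mapped to
  integers `clip(round(21 + 5*raw), 10, 40)`; the total is the subscale sum,
  landing near the familiar BIS-11 range (totals around 63). Defaults:
  loadings (0.7, 0.8, 0.6), noise_sd 0.6 — moderate, realistically noisy
  loadings of three correlated facets on one trait. Age ~ U{18..33}, sex ~
  Bernoulli(10/24), head size ~ N(1400, 100) cm³, all independent of the
  trait (they are pure covariates).
- **Geometry.** The atlas packs margin-separated cuboids into a lattice in
  the left half of the grid and mirrors them to the right; every ROI has
  ≥ 50 voxels or generation fails loudly. The default grid is 24×32×32 at
  2 mm, which fits the 23-ROIs-per-hemisphere (1 seed + 22 targets) scheme
  with ROIs of ~200 voxels.
- **Reproducibility.** All randomness flows from one cohort seed through
  four fixed-offset substreams (trait, ROI parameters, voxels, behavior), so
  a cohort is bit-reproducible and e.g. the behavioral draw does not change
  when the grid does.

What the generator does **not** emulate: cortical anatomy and folding, T1
contrast, registration error, scanner noise, spatial autocorrelation of GM
values (voxels are i.i.d. within ROI; apply `smooth_gaussian` afterwards if
correlation is wanted), realistic covariate–trait confounding, or
atlas misparcellation. Passing tests therefore demonstrate that the
estimator and statistics behave correctly under their stated model — not
that real VBM data satisfy that model.

## Simulation sizes used by the test suite

Monte-Carlo suites run at reduced, pre-calibrated sizes chosen to keep the
full suite fast while leaving comfortable margins: null-coupling type-I
error uses 500 cohorts of 12 subjects with 5 ROIs per hemisphere on a 16³
grid (the planted-pair test's rejection rate is compared with binomial 95%
bounds around 0.05; rates over three independent 500-cohort replicates
during calibration were 0.044–0.060); monotone recovery uses 10 cohorts of
40 subjects per coupling value in {−0.9, −0.5, 0, 0.5, 0.9}; full-atlas
detection uses 24-subject cohorts at coupling 0.9, noise 0.25 (15/15
calibration seeds put the planted connection in the FDR-passing set).
Roughly 1 null cohort in 500 draws a constant sex covariate at n = 12; the
covariate matrix is then rank-deficient, the scan correctly refuses it, and
simulations skip and count such cohorts.

## Numerical and degenerate-input policy

- Densities are compared only on identical grids; mismatched grids raise.
- `KLsym` is clamped at 0 from below (it can only go negative by floating
  rounding) and short-circuits to exactly 0 for bit-identical densities, so
  `MC = 1` is exact at identity.
- Constant regional samples, empty ROIs, rank-deficient covariates,
  |r| = 1 in the Fisher transform, and n ≤ k + 3 are all hard errors.
- Perfectly collinear mediation designs (e.g. M identical to X) are handled
  with pseudoinverse-based standard errors; the c = c′ + ab identity still
  holds through the minimum-norm fit.

## Known limitations

- MC depends on distribution shape only; two regions with identical value
  histograms in completely different spatial arrangements have MC = 1.
- The KL→similarity map is a convention; alternative maps reorder nothing
  (both built-ins are strictly decreasing in KLsym) but change the scale.
- The bootstrap mediation CI at n = 24 is wide, and when the "total" score
  is mediated by one of its own components, X and M are intrinsically
  collinear; interpret c′ cautiously there.
- No spatial resampling: volumes and atlas must share a grid (checked, not
  fixed).
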