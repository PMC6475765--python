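# Methods

`roirates` implements the ROI-level statistical machinery of a longitudinal
multimodal neuroimaging analysis of atypical Alzheimer's disease: biomarker
quantification, a Bayesian hierarchical model of regional annualized change,
posterior lobe comparisons, and cross-modal association analyses, together
with a synthetic-cohort generator that provides ground truth for all of it.

## Quantification

Regional tau-PET uptake is summarized as the median over an ROI's voxels
restricted to a grey-matter tissue mask (`gm_probability > 0.5` by default;
the threshold is configurable because segmentation-based masking conventions
vary).  SUVR divides each ROI median by the median uptake in cerebellar crus
grey matter, so the reference region has SUVR 1 identically.  Annualized
SUVR change is `(followup − baseline) / (interval_days / 365.25)`;
annualized log-Jacobians are `log_jacobian / interval_days × 365.25`
(interpretable as annual percent grey-matter volume change for small
deformations — deformation *estimation* is out of scope, the package
consumes log-Jacobian values).  ROI grey-matter volumes are normalized by
total intracranial volume.  Amyloid positivity uses a global SUVR cut-point
of 1.42; the boundary is treated as inclusive (≥ 1.42 → positive), a choice
the source procedure leaves open.  A year is 365.25 days everywhere.

## Hierarchical change model

For subject *i* in group *g(i)* ∈ {LPA, PCA, CU} with decade-scaled centered
age *x_i = (age_i − 65)/10*:

    y_ir = α_{g(i),r} + β_{g(i),r} · x_i + ε_ir,   ε_ir ~ N(0, σ)
    α_{g,·} ~ N(μ^α_g, τ^α_g),   β_{g,·} ~ N(μ^β_g, τ^β_g)
    μ ~ N(0, 1),   τ, σ ~ half-N(0, 1)

α is the annualized change at age 65 per region (SUVR/yr for tau, %/yr for
volume); β is the per-decade age effect.  Outcomes are modeled on their
native scales: the standard-normal hypermeans and half-normal scales are
weakly informative at both magnitudes, so no standardization is applied.

The residual term is one shared σ across regions and groups by default; a
per-region σ is available behind `per_region_sigma=True`.  The observation
model only says "a random error term", so shared σ is the simplest
consistent structure, and it matches the generator's default.

**Sampler.** Blocked Gibbs: the per-group (α_r, β_r) pairs are conjugate
bivariate-normal updates, vectorized across all groups and regions via
sufficient statistics (so per-iteration cost is independent of the number
of subjects); hypermeans are conjugate univariate normals; the
half-normal-prior scales (τ, σ) are updated by univariate slice sampling
(stepping-out with shrinkage; the step width adapts to the current state
because the scales live on very different magnitudes).  No external
probabilistic-programming dependency is used.  Chains are initialized
overdispersed from the priors (hypermeans ~ N(0,1), scales ~ |N(0,1)|+0.1)
with distinct per-chain seeds spawned from the master seed via
`numpy.random.SeedSequence`.

**Schedules.** The full-scale profile runs 200 chains of 80,000 draws
thinned to every 40th with 15,000 burn-in discarded.  Reading 80,000 as the
post-burn-in length retains 200 × 80,000/40 = 400,000 draws, consistent
with the posterior sample size the analysis is designed to produce, so
that is the default reading (`chain_length_includes_burn_in=False`); the
alternative reading is exposed but not silently reconciled.  The desk
profile (4 chains × 10,000, thin 10, burn-in 2,000 → 4,000 retained draws,
about 8 s for the 75-subject × 84-ROI design on one core) is used for
tests, replicate calibration and the demo pipeline; all problem sizes used
by the test suite and acceptance script are stated in their docstrings.

**Posterior functionals.** The atypical-AD effect pools LPA and PCA per
draw with sample-size weights (18 and 12 at study dimensions); contrasts
versus controls subtract the CU draw per region at the age center (for α)
and per decade (for β).  Region summaries are empirical quantiles at
{2.5, 10, 50, 90, 97.5}%, i.e. the 80% and 95% posterior bars, using
linear interpolation of order statistics.  Convergence is reported as the
classical Gelman–Rubin factor √(((n−1)/n·W + B/n)/W) per parameter.

## Lobe comparisons

Regional contrast draws are averaged (unweighted) within each of 8 lobes —
frontal, sensorimotor, medial/lateral temporal, medial/lateral parietal,
medial/lateral occipital — and compared pairwise: entry (row, col) is the
fraction of draws in which the column lobe's average change exceeds the
row lobe's.  Tied draws count 0.5 to each side, preserving the complement
identity p[i,j] + p[j,i] = 1 exactly.  The packaged 84-ROI → 8-lobe map
(42 bilateral region pairs) is a documented convention, user-overridable,
since the original atlas assignment is not published.  Display output
clips to "<0.001"/">0.999"; raw probabilities are retained in machine
output.  No multiplicity adjustment is applied across lobe pairs.

## Association analyses

**Partial correlations.** Each matrix entry is the Pearson correlation of
the residuals of one X column and one Y column after OLS adjustment for
the covariates (with intercept).  The default covariate is baseline age —
the only covariate the surrounding analyses use — and is configurable,
including none.  Constant columns yield NaN entries with a warning rather
than silent zeros.

**Permutation FWE.** Max-statistic (maxT) correction over the whole
matrix: rows of the *residualized* Y are permuted (Freedman–Lane style, so
covariate structure is preserved), the full |r| matrix is recomputed per
permutation, and `p_adj = (1 + #{perm max ≥ |r_obs|}) / (n_perm + 1)`, so
the attainable minimum is 1/(n_perm+1).  Per-matrix (not per-row) control
is implemented.  Defaults: 10,000 permutations, 1,000 in the desk profile.

**Sparse CCA.** Penalized matrix decomposition of the standardized
cross-covariance Z = XᵀY/(n−1): alternate u ← P(Zv), v ← P(Zᵀu) where P
soft-thresholds and renormalizes under ‖·‖₂ ≤ 1 and ‖·‖₁ ≤ c with
c = penalty·√dim, the threshold found by bisection so the L1 constraint is
met with equality when active (budgets below 1 are infeasible for a
unit-L2 vector and are clamped to 1).  Convergence tolerance 1e-6, at most
200 iterations; non-convergence returns the best iterate with a flag.
Subsequent components come from deflation Z ← Z − d·uvᵀ, d = uᵀZv.
Initialization is the leading right singular vector of (the deflated) Z —
deterministic, so seeds matter only for optional restarts.  Each pair is
oriented so the largest-magnitude u entry is positive.  The default lasso
penalty is 0.2 on both datasets; two components are retained by default
(only the first dimension is typically interpreted; the count is
configurable).  The reported correlation is the Pearson correlation of the
canonical variates Xu and Yv.

## Synthetic cohorts and phantoms

The generator is the exact generative counterpart of the hierarchical
model.  Defaults mirror the study conditions: 18 LPA + 12 PCA + 45 CU
subjects, 84 ROIs, baseline ages uniform on (53, 80) years, scan intervals
uniform on (348, 406) days.  Group-level defaults for tau (SUVR/yr):
intercept means 0.08/0.07/0.01 (LPA/PCA/CU) with sds 0.03/0.03/0.01, decade
slopes −0.03/−0.03/0 with sds 0.01/0.01/0.005, residual sd 0.05, chosen to
sit inside the reported envelope of regional tau accumulation rates (up to
~0.14 SUVR/yr relative to controls) and decade effects (up to ~0.08 SUVR).
The volume-modality defaults used by the pipeline are −1.2/−1.3/−0.2 %/yr
with positive decade slopes (older patients atrophy more slowly).
Measurement noise enters the follow-up value scaled by the interval, so
observed annualized change = true change + N(0, residual_sd) — the
simplest structure consistent with the model's single residual term.  The
residual structure (shared vs per-region sd) is selectable; shared is the
default, matching the model.

What the generator does *not* emulate: PET noise physics, spatial
autocorrelation between ROIs, longitudinal reference-region drift, and
missing follow-ups.  Passing recovery/coverage tests therefore demonstrate
correctness of the estimation machinery under the model's own assumptions,
not robustness to real-data violations of them.

Voxel phantoms place each ROI (plus one reference region) in a disjoint
3×3×1 block; five of the nine voxels lie inside the tissue mask (gm 0.9)
and are constructed so their median equals the target exactly (odd voxel
count, middle order statistic shifted onto the target), while the other
four carry low gm probability and corrupted uptake so masking is actually
exercised.  Construction + extraction round-trips are exact, not
approximate.

## Numerical choices and edge cases

- Exactly noise-free data make the conditional posterior of σ improper at
  zero (the likelihood term −N·log σ diverges); recovery tests therefore
  use a tiny positive residual sd (1e-3), far below their tolerance.
- Quantiles use linear interpolation of order statistics (tie-free).
- Region summaries warn (and proceed) below 100 retained draws; lobe
  comparison matrices refuse fewer than 100 draws.
- Annualized-change computations reject non-positive intervals; SUVR
  computation rejects non-positive reference medians; empty-after-masking
  ROIs raise an error naming the ROI.
- All randomness descends from a single master seed: pipeline stages use
  fixed documented offsets, MCMC chains use spawned `SeedSequence` children.

## Pipeline and provenance

`run_pipeline` executes simulate → quantify → fit → compare-lobes →
associate into one run directory (`cohort/`, `posterior/`, `lobes/`,
`associations/`, `log.txt`, `provenance.json`).  The provenance record
(config, config hash, master seed, per-stage seeds, package version, wall
times) suffices to re-create any output; reruns with the same config are
bit-identical.

## Known limitations

- The ROI→lobe map is a convention, not the original atlas assignment;
  lobe-level numbers on real data will depend on the user's map.
- The sampler is written for this model family; it is not a general PPL.
- Voxel-wise analyses, image registration/segmentation, deformation
  estimation and partial-volume correction are intentionally out of scope.
- SCCA component selection (beyond the default two) and inference on
  canonical weights are not provided, mirroring the source analysis.
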