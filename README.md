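# roirates

ROI-level statistical machinery for longitudinal multimodal neuroimaging of
atypical Alzheimer's disease (logopenic progressive aphasia, LPA, and
posterior cortical atrophy, PCA, versus cognitively unimpaired controls):

- **Quantification** — tissue-masked median ROI uptake, SUVR against a
  cerebellar-crus reference, annualized SUVR change, annualized
  log-Jacobians (percent volume change), intracranial-volume normalization,
  and amyloid-positivity calls (cut-point 1.42).
- **Hierarchical change model** — a Bayesian hierarchical regression of
  regional annualized change `y_ir = α_{g,r} + β_{g,r}·(age_i − 65)/10 + ε_ir`
  with group-specific regional random intercepts α, per-decade age effects
  β, N(0,1)/half-N(0,1) hyperpriors, fitted by a self-contained blocked
  Gibbs sampler (conjugate normal blocks, slice updates for the scales),
  with Gelman–Rubin diagnostics, sample-size-weighted LPA/PCA pooling and
  contrasts versus controls.
- **Lobe comparisons** — posterior probabilities that one of 8 lobes
  changes faster than another, from per-draw lobe averages.
- **Associations** — partial Pearson correlation matrices with max-statistic
  permutation family-wise error correction, and sparse canonical
  correlation analysis via penalized matrix decomposition (lasso penalty
  0.2 by default).
- **Synthetic cohorts & phantoms** — a generative mirror of the model at
  study dimensions (18 LPA / 12 PCA / 45 CU, 84 ROIs) with recorded ground
  truth, and voxel phantoms whose masked ROI medians are exact by
  construction.

It is aimed at neuroimaging statisticians who want the ROI-level analysis
chain as tested, reusable components with sklearn-style estimators
(`HierarchicalChangeModel`, `SparseCCA`, `PartialCorrelationFWE`) plus thin
functional wrappers. See `docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
from roirates import (SimulationParams, generate_cohort, build_model_input,
                      HierarchicalSpec, fit_mcmc, pooled_atypical_effect,
                      relative_to_controls, summarize_regions,
                      lobe_average, comparison_matrix)

cohort = generate_cohort(SimulationParams(seed=42))      # 75 subjects x 84 ROIs
design = build_model_input(cohort)
draws = fit_mcmc(HierarchicalSpec.desk(seed=7), design)  # 4 chains, 4000 draws
pooled = pooled_atypical_effect(draws, n_lpa=18, n_pca=12)
contrast = relative_to_controls(draws, pooled)           # patients minus controls
print(summarize_regions(contrast["alpha"], design.rois).head(4).round(3))
```

```
                                q2.5    q10  median    q90  q97.5
roi
left_superior_frontal          0.059  0.066   0.079  0.092  0.099
right_superior_frontal         0.031  0.038   0.051  0.064  0.071
left_superior_frontal_medial   0.037  0.044   0.057  0.070  0.076
right_superior_frontal_medial  0.062  0.069   0.081  0.095  0.101
```

Each row is one region's posterior for the annualized tau-SUVR change in
atypical AD relative to controls at age 65: the median with 80% (q10–q90)
and 95% (q2.5–q97.5) posterior intervals, in SUVR/yr.  Here the generator's
true patient-minus-control gap is ≈ 0.065 SUVR/yr, and the intervals cover
it.  Convergence: `draws.hyper_rhat()` reports a maximum hypermean R-hat of
1.002 for this fit.

Reducing the same contrast draws to lobes:

```python
lobe_draws, order = lobe_average(contrast["alpha"], design.rois)
print(comparison_matrix(lobe_draws, order).display().iloc[:3, :3])
```

```
                frontal sensorimotor medial temporal
frontal                        0.816           0.048
sensorimotor      0.184                        0.015
medial temporal   0.952        0.985
```

Entry (row, col) is the posterior probability that the column lobe's
average annualized change exceeds the row lobe's (rows and columns sum to
one pairwise).

The same pipeline runs end-to-end from the command line:

```bash
roirates run-all --out runs/demo --seed 1      # simulate → quantify → fit →
                                               # compare-lobes → associate
roirates simulate --seed 1 --out cohort.csv
roirates fit --cohort cohort.csv --profile desk --seed 1 --out posterior/
```

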