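# sclpipe

Cross-group psychometrics for short ordinal symptom scales.

`sclpipe` is for researchers who work with brief ordinal self-report
instruments — the motivating case is an 8-item psychosomatic complaint
checklist (headache, stomachache, backache, feeling low, irritability,
nervousness, sleep difficulties, dizziness; five frequency categories
coded 0–4) administered to adolescents in dozens of countries — and who
need to answer, per group and across groups:

1. **Is the scale unidimensional?** Exploratory graph analysis (EGA):
   polychoric correlations → EBIC-selected graphical lasso →
   walktrap communities.
2. **Does the graded response model fit?** Marginal-ML GRM
   (`P(X_j ≥ k | θ) = logistic(a_j(θ − b_jk))`) with limited-information
   C2 fit indices (RMSEA, SRMR, CFI, TLI), signed Cramér's V local-
   dependence residuals, generalized S-X² item fit, monotonicity
   residual curves, ICC/TCC/IIF/TIF, EAP scores, empirical marginal
   reliability, and Wright maps.
3. **Is it unidimensional *enough*?** Post-hoc bifactor GRM with
   marginal-slope comparison, average relative bias, and the
   ECV / PUC / H / FD indices.
4. **Are parameters invariant across groups?** Configural / metric /
   scalar multigroup GRM with pooled C2, then alignment optimization
   (simplicity loss `f(x) = (x² + 10⁻⁴)^¼`, FIXED/FREE, invariance
   flagging at α = 0.01 / 0.001, R² indices, Monte-Carlo ranking
   stability).
5. **What do the differences mean for scores?** Pairwise compensatory /
   non-compensatory differential test functioning (sDRF / uDRF with
   bootstrap CIs) and factor-score vs sum-score comparisons.

A synthetic-data generator reproduces the statistical structure such
surveys show (right-skewed items, a dominant general factor with a
psychological item cluster, group-level non-invariance), so the entire
chain runs and is tested without restricted survey data.

## Worked example

```python
import numpy as np
from sclpipe import (make_hbsc_like_defaults, make_multigroup_scenario,
                     fit_grm, c2_fit, empirical_marginal_reliability,
                     fit_multigroup, multigroup_c2, align, invariance_r2,
                     pairwise_dtf)

# eight groups of n = 1000 with spread latent means/variances, no DIF
spec = make_hbsc_like_defaults(n_groups=8, n_per_group=1000,
                               bifactor=False, with_dif=False, seed=0)
data, truth = make_multigroup_scenario(spec)

one = data.group_data("G01")
fit = fit_grm(one.responses, item_names=data.item_names)
fi = c2_fit(fit)
print(f"C2 = {fi.c2:.1f} on df = {fi.df}, RMSEA = {fi.rmsea:.3f}, "
      f"rho = {empirical_marginal_reliability(fit):.3f}")

config = fit_multigroup(data, "configural")
print(f"configural df = {multigroup_c2(config).df}")

aligned = align(config, method="fixed", reference="G01")
summary = invariance_r2(aligned)
print(f"mean R2 = {summary.R2.mean():.3f}, "
      f"fully invariant rows: {(summary.n_invariant == 8).mean():.0%}")
print("uDRF range:", np.round([pairwise_dtf(aligned)['summary'][k]
      for k in ('uDRF_min', 'uDRF_max')], 3))
```

Output on this seed:

```
C2 = 19.6 on df = 20, RMSEA = 0.000, rho = 0.828
configural df = 160
mean R2 = 0.867, fully invariant rows: 100%
uDRF range: [0.035 0.27 ]
```

Read: the single-group GRM fits (C2 at its 20 degrees of freedom —
60 reduced margins minus 40 item parameters), score reliability is 0.83,
no parameter row is flagged non-invariant on invariant data, and the
expected-test-score differences between groups stay small on the 0–32
score range once latent means/variances are aligned. The mean R² of 0.87
reflects that with no DIF most of the (small, noise-driven) configural
spread is absorbed by the latent moments.

The same flow is available from the shell:

```bash
sclpipe simulate data.csv --n-groups 8 --n-per-group 1000 --seed 0
sclpipe run data.csv --out report/        # JSON + TSV tables + plots
sclpipe align data.csv --method fixed --mc-reps 50
```

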