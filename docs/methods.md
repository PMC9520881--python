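# Methods

`sclpipe` implements the analysis chain used to evaluate short ordinal
self-report scales — the motivating case is an 8-item psychosomatic
complaint checklist with five ordered response categories administered in
many countries — covering dimensionality assessment, item response
modelling with limited-information diagnostics, bifactor screening,
multigroup measurement invariance, alignment, and differential test
functioning. This note documents the models, the estimators, the numerical
choices, and what the synthetic-data generator does and does not emulate.

## The graded response model

For item j with K ordered categories (coded 0..K−1) the cumulative
response probabilities are logistic in the latent trait θ:

    P(X_j ≥ k | θ) = 1 / (1 + exp(−a_j (θ − b_jk))),   k = 1..K−1,

with discrimination a_j > 0 and strictly increasing thresholds b_jk. The
package works on the logistic metric (D = 1) throughout; the constant
D = 1.702 appears only where slopes are converted to normal-ogive
standardized loadings for the bifactor indices.

Estimation is marginal maximum likelihood with a Bock–Aitkin EM: θ is
integrated over 61 equally spaced quadrature nodes on [−6, 6] carrying
renormalized standard-normal mass (the grid density and span are
configurable). The E-step computes each response pattern's posterior over
the nodes; the M-step maximizes the expected complete-data log-likelihood
per item by Newton steps with step-halving in the intercept
parametrization (c_k = −a b_k, kept strictly decreasing), which preserves
the EM monotonicity of the marginal log-likelihood. Convergence is
declared when the largest absolute parameter change falls below 1e−4
(at most 500 cycles). Slopes are initialized at 1 and intercepts at
inverse-normal marginal proportions; slopes that run away past 25 are
capped and flagged. Frequency weights enter the E-step as row
multiplicities; missing responses (sentinel −1) drop out of the
likelihood.

Standard errors use the empirical cross-product form of the observed
information: per-person score vectors are obtained from the Fisher
identity (posterior-weighted complete-data gradients), their weighted
outer-product sum is inverted, and the (a, c) covariance is mapped to the
(a, b) metric by the delta method. The full per-group covariance matrix is
retained because the alignment stage propagates it.

Score-level derivations follow Samejima: item expected scores and their
sum (ICC/TCC), item/test information `I_j(θ) = Σ_k (P′_jk)² / P_jk`,
expected a-posteriori (EAP) trait estimates with posterior SDs, empirical
marginal reliability ρ = Var(EAP)/(Var(EAP) + mean posterior variance),
and Wright-map data (EAP histogram plus threshold locations).

## Limited-information model fit

The global statistic is a C2-type quadratic form on reduced margins: per
item the K−1 cumulative category proportions, plus one bivariate summary
per item pair, the cross-moment E[X_i X_j] — 60 statistics for 8
five-category items. With e the observed-minus-implied statistics, Γ
their model-implied asymptotic covariance (computed exactly by quadrature
using conditional independence given θ), and Δ the Jacobian of the implied
statistics in the free parameters (central differences), the statistic

    C2 = N e′ [Γ⁻¹ − Γ⁻¹Δ(Δ′Γ⁻¹Δ)⁻¹Δ′Γ⁻¹] e

is asymptotically chi-square because the weight matrix annihilates the
model Jacobian. Published C2 constructions differ in the choice of the
bivariate reduction and weight; rather than claiming equivalence with any
particular implementation, the package verifies type-I calibration by
simulation (rejection rate ≈ α on self-generated data, 200 replicates).

Degrees of freedom are counted as (#margin statistics) − (#free item
parameters), with latent means/variances excluded from the count. This
convention gives 20 for one group of 8 five-category items and 640 / 888 /
1880 for configural / metric / scalar models across 32 groups. In the
multigroup statistic the free latent parameters do enter the Jacobian
projection (so the statistic stays first-order insensitive to their
estimation); only the reported df follows the counting convention.

RMSEA = sqrt(max(C2 − df, 0)/(df (N−1))) with a 90% CI by noncentral
chi-square inversion; CFI/TLI compare against a zero-slope independence
baseline with free thresholds; SRMR is the root-mean-square difference
between observed and model-implied Pearson inter-item correlations
(reported per group in multigroup models). A singular weight matrix gets
an escalating ridge (1e−8, 1e−6), logged on the result.

Local diagnostics: signed Cramér's V residuals per item pair (Pearson X²
of observed vs implied bivariate tables, signed by the residual score
covariance, tiny-expected cells pooled); generalized S-X² item fit via the
polytomous Lord–Wingersky summed-score recursion with adjacent score
groups (and, within a group, adjacent categories) collapsed until every
expected count reaches 1, df = free cells − item parameters, with
item-level RMSEA as effect size; and monotonicity raw-residual curves. For
the latter, persons are binned by the EAP computed from the *other* items
and compared with the ICC averaged over that rest-score posterior — under
the model E[X_j | rest] equals that expectation exactly, so residuals are
pure misfit rather than selection artifacts (binning on a score involving
the item itself produces spurious residuals of ±0.3 even under the true
model; an early implementation also showed that quantile edges can split
floating-point ties exactly along the studied item's response, which the
rest-pattern collapsing avoids).

## Dimensionality: exploratory graph analysis

Polychoric correlations use the two-step estimator — thresholds from
inverse-normal cumulative marginals, then per-pair ML of the bivariate
normal over the contingency table. Rectangle probabilities use the
deterministic reduction Φ₂(h, k, ρ) = Φ(h)Φ(k) + ∫₀^ρ φ₂(h, k, r) dr with
64-point Gauss–Legendre (absolute error well below 1e−10). Unidentified
pairs fall back to 0 with a warning; the matrix is repaired to PSD by
eigenvalue clipping at 1e−8 when needed (logged), since the graphical
lasso requires PSD input.

EGA submits the polychoric matrix to a graphical lasso over 100
log-spaced penalties from 0.01·ρ_max to ρ_max, selects by extended BIC
with γ = 0.5, converts the selected precision matrix to partial
correlations, and detects communities by walktrap (4 steps) on absolute
edge weights. The number of non-empty communities is the estimated
dimensionality; modularity ties resolve toward fewer communities. These
settings are the common defaults of the network-psychometrics ecosystem;
all are surfaced in the configuration.

## Bifactor screening ("unidimensional enough")

The bifactor GRM adds one orthogonal specific factor per item cluster:
z_jk = a_gj(θ_g − b_jk) + a_sj θ_sc, with independent standard-normal
factors. Estimation integrates over (general × one specific at a time)
31-node-per-dimension quadrature; the marginal likelihood is maximized
directly by L-BFGS-B with its exact gradient from the EM identity
(expected complete-data gradient at the current posterior), with
thresholds kept ordered through a log-gap parametrization. Direct
maximization replaced a plain EM that crawled along the nearly flat
specific-slope directions. Items may be assigned no specific factor
(cluster id −1) and singleton clusters get their specific slope fixed at
zero; both restrictions matter because a bifactor model in which every
item carries a free specific slope across exactly two clusters is only
weakly identified — the likelihood has a near-flat ridge trading general
against specific slopes, and estimates on that ridge should be read as
descriptive, which is how the comparison indices use them.

The comparison toolkit converts slopes to normal-ogive loadings
λ = (a/1.702)/sqrt(1 + (a_g/1.702)² + (a_s/1.702)²) and reports: marginal
discriminations 1.702·λ_g/sqrt(1 − λ_g²) (exactly a_g when a_s = 0);
average relative bias mean |a_uni − a_marg|/a_marg × 100; ECV
(general and per-specific shares of common variance, summing to one), PUC
(cross-cluster pair share, a pure function of the mask), construct
replicability H = [1 + (Σ λ_g²/(1−λ_g²))⁻¹]⁻¹, and factor determinacy FD
from the model-implied latent-response covariance; plus TCC/TIF on the
general dimension with specifics integrated out, the EAP score
correlation between models, and the reliability change. The pipeline's
inclusion rule is average relative bias < 20%, with 10–15% the
conventional negligible band.

Note one sampling property: when the true specific slopes are zero the
likelihood is an even function of each cluster's specific-slope vector, so
the score vanishes at zero and the MLE magnitude shrinks only at rate
n^(−1/4); at n = 3000 fitted |a_s| around 0.5 with a log-likelihood gain
of ~1.5 over the nested unidimensional fit is the expected null behavior,
while the marginal slopes, scores, and reliability still reproduce the
unidimensional solution. Tests therefore check the substantive reduction,
not a small |a_s|.

## Multigroup invariance and alignment

The configural model fits each group separately with N(0, 1) latent
priors; metric equates slopes (variances free except the first group's);
scalar equates slopes and thresholds (means and variances free except the
first group's, fixed at 0 and 1). Equality constraints are handled inside
the EM M-step: per-group Newton updates of free thresholds alternate with
a one-dimensional Newton update of each shared slope on the pooled
expected counts; latent moments update as posterior means/variances.
Because the latent scale is identified only through the reference group,
the shared-slope estimates carry that single group's sampling noise as a
common scale factor: at n = 1000 per group their RMSE concentrates around
0.1 (scale-free slope ratios are much tighter), shrinking to ~0.03 at
n = 4000 per group.

Alignment starts from the configural solution and re-expresses it through
group factor moments, a′ = a/√ψ_g and b′ = √ψ_g b + α_g, choosing the free
(α_g, log ψ_g) to minimize Σ_rows Σ_{g<g′} √(N_g N_g′) f(p_g − p_g′) with
the simplicity kernel f(x) = (x² + 0.0001)^(1/4) (so f(0) = 0.1). The
optimizer is L-BFGS-B with five seeded starts; pair weights are
normalized by their mean (scale-irrelevant for the argmin). FIXED pins a
reference group at (0, 1) — chosen, when unspecified, as the group whose
freely estimated mean is closest to zero in a FREE pre-run; FREE fixes
only ψ₁ = 1 and is flagged "poorly identified" (recommending FIXED) when
the loss Hessian's condition number exceeds 1e8, since the mean vector
has a near-flat translation direction. The aligned model reproduces the
configural likelihood exactly (the re-expression is a latent change of
variables; asserted to 1e−8 using transformed quadrature nodes).

Invariance flagging: pairwise z-tests on aligned parameters at α = 0.01
(SEs by the delta method from the configural observed information) seed
the invariant set with the largest connected component of non-significant
pairs; each group is then retested against the sample-size-weighted
invariant-set average at α = 0.001 until the set stabilizes. The summary
table reports weighted averages/variances across invariant and all
groups, counts/percentages, and the R² index: one minus the ratio of the
weighted variance of configural parameters around the values implied by
back-transforming the invariant-set average through each group's
(α_g, ψ_g) to their weighted variance around the weighted mean — near 1
when cross-group spread is pure latent-scale variation, near 0 when it is
pure DIF (clipped to [0, 1], raw value retained).

The Monte-Carlo stability study re-simulates every group from the aligned
estimates at the real group sizes, refits and re-aligns per replicate,
and reports (i) the correlation between generating means and
replication-averaged estimates — ranking stability, with ≥ 0.98 the
conventional trustworthiness bar — and (ii) 95% CI coverage per group.
The SE of each aligned mean comes from an implicit-function delta method:
at the loss optimum ∂x/∂p = −H_xx⁻¹ H_xp, propagated through the
configural covariance blocks. This SE is computed once (replicates share
the design) and is mildly conservative (observed coverage 0.97–1.00 at 50
replicates). The pipeline triggers the study when more than 25% of
parameter rows are flagged non-invariant; its default of 50 replicates is
a scaled-down version of the conventional 500-run design and reproduces
the same ranking-correlation decision on the scenarios the generator
covers.

## Differential test functioning and score comparisons

For an aligned group pair, sDRF and uDRF integrate the signed and
absolute expected-test-score difference over a latent weight density —
standard normal on the aligned metric by default, optionally the focal
group's N(α_f, ψ_f); which density the original analyses weighted by is
not documented, so both are exposed. Integration is Simpson's rule on a
201-point lattice over [−6, 6] (agrees with a 100,001-point trapezoid to
~1e−12; doubling the lattice changes results by far less than 1e−4).
Positive sDRF means the reference group scores higher at equal trait
levels, and uDRF ≥ |sDRF| always. CIs use a seeded parametric bootstrap
(399 draws, 99% level) from the aligned parameter SEs with re-sorted
thresholds. Pairwise DTF exploits antisymmetry/symmetry to compute each
unordered pair once. The factor-score/sum-score comparison computes EAPs
under each group's aligned parameters with the group's own latent prior,
regresses sum scores on them per group, and correlates group means across
groups.

## The synthetic-data generator

The generator emulates the structure of large multi-country
symptom-checklist data: 8 items × 5 categories; default discriminations
(1.66, 1.48, 1.23, 2.31, 2.13, 2.01, 1.46, 1.79) and right-shifted
default thresholds taken from published cross-group weighted-average
estimates for this instrument, so the psychological items (4–6) are the
most discriminating and simulated item scores are positively skewed with
polychoric inter-item correlations roughly 0.2–0.85; group latent means
spread over [−0.5, 0.5] and variances over [0.8, 1.25] with the first
group on the reference scale (0, 1); optional bifactor structure with a
somatic cluster (items 1–3, 7, 8; default specific slope 0.45) and a
psychological cluster (items 4–6; default 0.95); and targeted
non-invariance injected as additive offsets on the difficulty metric
(defaults: a +0.5 first-threshold shift on item 5 in one group, a +0.6
slope shift on item 6 in another, a −0.4 shift on item 7's third
threshold in a third). Sampling is inverse-CDF from the exact model
probabilities; each group draws from an independent child stream of the
master seed, so adding a group never perturbs the others.

What it does not emulate: survey design effects (clustering,
stratification — only row weights exist), item-level missingness
mechanisms beyond MCAR deletion patterns, non-normal latent traits,
age/gender covariate structure, and response styles. Passing tests
therefore demonstrate correctness of the estimators and decision logic
under the stated generating conditions, not robustness to those
real-data features.

## Problem sizes and defaults used in tests

Unit and acceptance checks run at deliberately modest sizes chosen to
make sampling error small relative to the asserted tolerances:
single-group recovery at n = 3000; multigroup scenarios at 8 groups ×
1000; type-I calibration with 200 replicates of n = 1000; alignment
flagging with 20 seeded replicates per scenario in the test suite (10 in
the reproduction script); ranking-stability with 50 Monte-Carlo
replicates. Tolerances in tests mirror the estimators'
verified sampling behavior at those sizes.

## Known limitations

* Standard errors are observed-information (cross-product) based; no
  design-robust (sandwich/MLR) correction is implemented.
* The C2 weight construction is one member of the published family;
  calibration is established by simulation, not algebraic equivalence
  with other software.
* Two-specific-cluster bifactor models with all specific slopes free are
  weakly identified (see above); indices derived from them are
  descriptive.
* The FREE alignment identification criterion (Hessian condition number
  > 1e8) is the package's own operationalization.
* Polychoric estimation assumes an underlying bivariate normal per pair;
  no polyserial or asymptotic-covariance (WLS) machinery is provided.
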