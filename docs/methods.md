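# Methods

This note records the models, the calibration of the synthetic-cohort
generator, and the numerical and design choices behind `csfpanel`, in
enough detail to reproduce or audit any stage.

## Synthetic cohorts

**What is emulated.** Only group-level summaries are available for the
cohorts the pipeline targets: per diagnostic group (AD, DLB, bvFTD, PNFA,
SD, controls) the median and interquartile range of each biomarker, the
number of subjects with that measurement, group sizes, and demographic
summaries (age median/IQR, % male, symptom-onset-to-LP months). The
generator reproduces exactly these features:

- **Marginals.** Each biomarker is log-normal within each group. From a
  published triple (median, Q1, Q3) the log-scale parameters are
  μ = ln(median) and σ = ln(Q3/Q1)/(2·z₀.₇₅), z₀.₇₅ ≈ 0.67449. This
  matches the median exactly and the interquartile *ratio* exactly; a
  two-parameter family cannot also pin both quartiles individually unless
  they are geometrically symmetric about the median. For the published
  rows the asymmetry is small (quartile error mostly ≤ 2%, the skewest
  NFL rows ≈ 7%). Log-normality itself is an assumption consistent with
  analysing these right-skewed assays on the log scale.
- **Dependence.** Between-biomarker correlations are not published, so a
  log-scale block structure is assumed: 0.5 within the amyloid-processing
  family (Aβ1–42, AβX-38/40/42, sAPPα/β), 0.7 between T-tau and
  P-tau-181, 0.3 otherwise (configurable; validated positive
  semi-definite at load). Ratios (T-tau/Aβ1–42, AβX-42/X-40) are *never
  drawn directly* — they are computed from generated constituents, so
  their spread depends on the assumed correlation and only approximates
  the published ratio summaries (observed within ~25%).
- **Demographics.** Age is normal matched to median/IQR and truncated
  below at 18 y (a log-normal would impose skew the published age
  summaries do not show); sex is Bernoulli(% male); disease duration is
  log-normal matched to its quartiles; MMSE is generated for table
  fidelity (rounded, clipped to 0–30) but unused downstream.
- **Missingness.** Values are deleted completely at random per group ×
  biomarker at rate 1 − n_available/n_group, from an independent stream
  per biomarker, after generation and before censoring. The validation
  cohort has no published per-group distributions; it inherits the
  test-cohort group distributions restricted to its five measured
  analytes, with whole-cohort availability fractions applied uniformly.
- **Detection limits.** Values are clamped to (0.1×, 10×) the pooled
  (size-weighted) median per biomarker — wide enough that censoring is
  exercised but rare, and configurable.
- **Confirmed sub-cohort.** 26 test-cohort subjects are flagged
  pathology/genetically confirmed (13 AD, 1 DLB, 9 bvFTD, 2 PNFA, 1 SD).

**What is not emulated**, and hence what passing tests do not show about
real data: true tail shape beyond the IQR (log-normal is imposed), real
between-assay dependence, batch/plate effects, any association between
missingness or censoring and disease severity, and within-group
diagnostic heterogeneity (e.g. comparator cases harbouring AD
co-pathology — precisely the feature thought to limit specificity against
DLB and PNFA in practice). Synthetic AUCs are therefore typically more
optimistic than clinical ones and are not a validation of the clinical
numbers, only of the machinery.

## Heteroscedastic group comparisons

Model: y_ij = m_g(i) + x_iᵀγ + e_i on natural-log concentrations, with
Var(e_i) = σ²_g(i) — one residual variance per diagnostic group.
Estimation is maximum likelihood by alternating weighted least squares
for (m, γ) and closed-form per-group variance updates (ML divisor n_g),
declared converged when successive log-likelihoods differ by < 1e-10
(cap 200 iterations; non-convergence is reported on the result, never
silently accepted). ML rather than REML is used so nested-model
likelihood-ratio tests are coherent; the global test compares against a
covariate-retaining equal-means null with the same variance structure,
referred to χ² with (groups − 1) df.

Numerical choice — variance floor: when a very small group's
covariate-adjusted values can be interpolated exactly, the group ML
variance collapses and the likelihood is unbounded. Group variances are
floored at max(1e-12, 1e-6 · var(y)) with a single warning per fit; the
scale-aware floor bounds the likelihood and restores convergence while
leaving the all-values-identical degenerate case (var(y) = 0) at the
absolute floor.

The three reported variants are: all groups including controls
(unadjusted), dementia-only (unadjusted), and dementia-only adjusted for
age (years, linear), sex (indicator) and onset-to-LP (months, linear).
Controls are excluded from the adjusted variant because they have no
disease duration. Pairwise contrasts are gated on the dementia-only
tests (unadjusted p < 0.05, or unadjusted p > 0.05 with adjusted
p < 0.05); when the gate passes, all 15 unordered pairs among the six
groups are tested as two-sided z-tests on log-scale mean differences from
the *single* all-groups unadjusted fit, so the 15 tests share one
variance estimate per group. Tiers are fixed thresholds, not adjusted
p-values: "+" at p < 0.05, "++" at p < 0.003 (0.05/15 rounded as
conventionally printed).

## ROC, cut-points and exact intervals

AUC is computed via midranks, algebraically identical to pair counting
with 0.5 credit for ties; a `direction` flag orients each biomarker so
the AD side counts as positive (lower for the amyloid measures and NFL,
higher for the tau measures, YKL-40 and the sAPP fragments; overridable,
or inferable from the data as the sign of the AD-vs-rest median
difference).

The cut-point at target sensitivity t (default 0.85) is the most
case-side observed AD value whose positivity fraction among AD cases is
≥ t, with positivity including equality with the threshold (ties are
measure-zero for continuous assays; including equality makes small
integer examples deterministic). Choosing an observed order statistic
keeps the estimate reproducible from data alone; making it a function of
the AD sample only keeps it identical across comparators, with
specificity the only comparator-dependent quantity. Among admissible
thresholds this choice simultaneously maximises specificity against any
comparator.

Binomial proportions carry Clopper–Pearson ("exact", conservative)
intervals by beta-quantile inversion, with the closed-form boundary cases
at k = 0 and k = n. The cut-point CI takes the exact interval (p_lo,
p_hi) for the positive count at the cut-point and maps each bound back to
the AD order statistic whose positivity fraction reaches it; the interval
therefore consists of observed concentrations and contains the cut-point.
A bootstrap alternative (resample AD values, percentile interval of the
re-estimated cut-point) is available behind `method="bootstrap"`; the
binomial mapping is the default.

Top-5 ranking: for a single-group comparison the candidate set is the
biomarkers with at least a "+" pairwise tier for that pair; for pooled
comparisons (AD vs non-AD dementia, AD vs all others) all biomarkers are
candidates. Ranking is by AUC descending, ties broken alphabetically for
determinism, at most five returned.

## Joint models, leave-one-out, bootstrap

Joint logistic models use natural-log concentrations (the same scale as
the group comparisons), complete cases across the included biomarker set
(excluded counts are logged), and are fitted only when both groups exceed
10 subjects. Fitting is IRLS with convergence at a maximum coefficient
change < 1e-8 (cap 100 iterations). Complete separation is detected as a
diverging coefficient norm, a singular working Hessian, or failure to
converge with saturated fitted probabilities; the model is then refitted
with a small ridge penalty (1e-4, intercept unpenalised) and the result
flagged.

Every subject receives an out-of-fold probability: the model is refitted
without that subject (warm-started at the full fit — identical optimum,
fewer iterations) and the held-out subject scored. The AUC of the pooled
LOO scores is the reported discrimination, with a bias-corrected (BC,
no acceleration term) percentile bootstrap CI: stratified resampling
within class, 2000 replications by default, z₀ from the fraction of
replicate AUCs below the point estimate (clipped half a replicate from
the boundary so the probit is finite). The joint model's specificity is
computed from the pooled LOO score vector: a fixed-sensitivity cut-point
is derived from the LOO scores of AD subjects (case side = higher
probability) and applied to the comparator scores — mirroring the
single-biomarker rule rather than re-deriving per-fold thresholds.

Known property: pooling leave-one-out scores biases AUC slightly
*downward* on uninformative predictors (a held-out case is scored by a
model trained with one fewer case, shifting its score toward the control
side, and vice versa). At n = 200 with two noise predictors the mean
pooled-LOO AUC is ≈ 0.45–0.46 rather than 0.50, while the in-sample AUC
is optimistic (≈ 0.55). The calibration suite asserts both the optimism
gap and centring; the centring assertion documents this inherent
pessimism of the pooled-LOO procedure.

## Validation transfer

Cut-points estimated on the test cohort are applied unchanged (never
refitted) to the validation cohort for the five transferable measures
(Aβ1–42, T-tau, P-tau-181 and the two ratios), for three comparisons:
AD vs controls, AD vs other dementias (DLB ∪ bvFTD ∪ PNFA ∪ SD), and AD
vs both combined. Analysis is complete-case per biomarker with
denominators reported per cell. The same computation restricted to the
confirmed sub-cohort yields the confirmed block; comparisons with no
comparator subjects there (controls are never autopsy-confirmed) are
omitted, and with ~26 subjects the exact intervals are necessarily wide.

## Reproducibility and problem sizes

Every random stage consumes a named child stream of one master seed
(numpy `SeedSequence.spawn`), recorded in the run log; a full `report`
run is bit-reproducible given the seed. The calibration suite uses
simulation sizes chosen to give tight Monte-Carlo bands at interactive
cost: 1000 random instances for the exact-oracle checks, 10000 draws per
setting for interval coverage, 2000 null replicates for the global-test
size, 200 seeds at n = 200 for the LOO study, and 500 datasets × 500
replicates for bootstrap coverage; generator recovery uses n = 100000
(marginals) and 50000 per group (closed-form AUC comparison).

## Limitations

- All distributional calibration is to medians/IQRs; any conclusion
  sensitive to tails beyond the quartiles is untested.
- The correlation structure is an assumption, flagged in the config;
  ratio-based results depend on it.
- The heteroscedastic LR test relies on asymptotic χ² calibration; with
  very small groups (SD, n = 7) its p-values are approximate, which is
  why the pairwise grid, not any single small-group p-value, should be
  read as the summary.
- The synthetic validation cohort shares its generating distributions
  with the test cohort, so transfer results demonstrate the mechanics of
  cut-point transfer, not between-laboratory robustness.
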