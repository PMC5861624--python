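# csfpanel

Diagnostic-accuracy analysis of an extended cerebrospinal-fluid (CSF)
biomarker panel for the differential diagnosis of Alzheimer's disease (AD).

Clinicians in specialist cognitive clinics must distinguish AD not only
from healthy ageing but from other neurodegenerative dementias — dementia
with Lewy bodies (DLB), behavioural-variant frontotemporal dementia
(bvFTD), progressive non-fluent aphasia (PNFA) and semantic dementia (SD).
`csfpanel` implements, as a tested and reusable pipeline, the statistical
workflow for evaluating how well a ten-analyte CSF panel (Aβ1–42, T-tau,
P-tau-181, NFL, YKL-40, AβX-38, AβX-40, AβX-42, sAPPα, sAPPβ) and two
derived ratios (T-tau/Aβ1–42 and AβX-42/X-40) separate AD from each
comparator group, and for transferring the resulting decision thresholds
to an independent cohort.

Because patient-level data from such clinics are not generally shareable,
the package includes a first-class synthetic-cohort generator calibrated
to published group summaries (per-group medians and interquartile ranges,
group sizes, per-biomarker availability), so every downstream stage is
runnable and testable without any download.

## The statistical core

- **Group comparisons.** Log-transformed concentrations are compared with
  a generalised least squares model allowing a *different residual
  variance in every diagnostic group* — an extension of one-way ANOVA that
  drops the equal-variance assumption. Fitting is by maximum likelihood;
  the global test is a likelihood-ratio test of equal group means
  (χ², df = groups − 1), run including controls, dementia-only, and
  dementia-only adjusted for age, sex and symptom-onset-to-LP time.
  Post-hoc pairwise z-contrasts over the 15 unordered group pairs are
  tiered at p < 0.05 ("+") and at the fixed Bonferroni threshold
  p < 0.003 = 0.05/15 ("++").
- **ROC analysis at fixed sensitivity.** The AUC is the tie-corrected
  Mann–Whitney probability P(case on the case side of a comparator). The
  decision threshold is not optimised freely: sensitivity is fixed at 85%
  and the cut-point is the most case-side observed AD value whose
  positivity fraction still meets the target — so it depends only on the
  AD sample and is identical for every comparator. Binomial uncertainty
  (sensitivity, specificity) uses conservative exact Clopper–Pearson
  intervals; the cut-point interval maps the exact sensitivity interval
  back onto the AD order statistics.
- **Multi-biomarker combinations.** Up to five best-performing biomarkers
  (by AUC, among those pairwise-significant for the comparison) enter a
  logistic model on log concentrations, fitted only when both groups
  exceed 10 subjects. Every subject is scored out-of-fold
  (leave-one-out), and the AUC of the pooled LOO scores carries a
  bias-corrected percentile bootstrap CI (stratified, 2000 replications).
- **Validation transfer.** Test-cohort cut-points are applied *unchanged*
  to the independent validation cohort and to the pathology/genetically
  confirmed sub-cohort, for AD vs controls, vs other dementias, and vs
  both combined.

See `docs/methods.md` for model details, generator assumptions and known
limitations.

## Worked example

Generate the default cohorts (275 test subjects, 143 validation subjects)
and estimate fixed-sensitivity cut-points for the five transferable
measures:

```sh
csfpanel simulate --seed 42 --test-out test_cohort.csv --validation-out validation_cohort.csv
csfpanel cutpoints --seed 42 --test-cohort test_cohort.csv --validation-cohort validation_cohort.csv \
    --biomarkers abeta_1_42,t_tau,p_tau_181,t_tau_abeta_1_42,abx42_abx40
```

```text
       biomarker direction glyph  cutpoint  ci_lower  ci_upper  achieved_sensitivity  n_cases
      abeta_1_42     lower     <   554.697   488.605   646.788                 0.853      156
           t_tau    higher     >   367.146   311.187   446.002                 0.853      156
       p_tau_181    higher     >    51.198    44.248    55.127                 0.851      114
t_tau_abeta_1_42    higher     >     1.106     0.986     1.297                 0.853      156
     abx42_abx40     lower     <     0.074     0.058     0.083                 0.851       87
```

Each row reads: a subject tests positive for AD when the value lies on
the case side of (or equal to) the cut-point — below 554.7 pg/mL for
Aβ1–42, above 367.1 pg/mL for T-tau, and so on. The cut-point is the
least extreme AD order statistic keeping at least 85% of AD cases
positive (`achieved_sensitivity` is the realised fraction, ≥ 0.85 by
construction); `ci_lower`/`ci_upper` map the exact binomial CI of that
fraction back to concentrations; `n_cases` is the number of AD subjects
with that measurement (missingness mirrors the per-biomarker availability
of the emulated cohort). Specificities against each comparator group at
these thresholds, AUC rankings, joint models and the validation transfer
are produced by `csfpanel report -o reports/`, which writes all five
report tables and a run log.

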