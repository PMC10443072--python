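# vcfval

Diagnostic-accuracy validation of patient-level **vertebral compression
fracture (VCF) detectors** against an adjudicated, dual-reader,
Genant-graded radiologist reference standard.

Opportunistic CT screening extracts fracture information from chest or
abdomen/pelvis scans performed for unrelated reasons. Automated detectors
emit one binary call per CT study (positive / negative, sometimes
non-evaluable), while radiologists grade each vertebra (T1–T12, L1–L5) on
the Genant semiquantitative scale (1 mild, 2 moderate, 3 severe). `vcfval`
implements the full statistical validation of such a detector for study
teams running reader studies: reference-standard construction with senior
adjudication, 2×2 cross-tabulation at several severity thresholds, exact
interval estimation, likelihood-ratio inference, per-vertebral-level
sensitivity, handling of non-evaluable studies, LR-precision sample sizing,
and inter-rater reliability — plus a synthetic cohort generator so the whole
analysis runs and is testable without any patient data.

## Statistics implemented

- **Operating characteristics.** Sensitivity `Se = TP/(TP+FN)`, specificity
  `Sp = TN/(FP+TN)`, predictive values; 95% CIs by the Clopper–Pearson exact
  binomial tail inversion.
- **Likelihood ratios.** `LR+ = Se/(1−Sp)`, `LR− = (1−Se)/Sp`, with
  log-method CIs from the delta-method variance
  `var(ln LR+) = 1/TP − 1/(TP+FN) + 1/FP − 1/(FP+TN)`.
- **Non-evaluable-inclusive sensitivity.** `Se_incl = Se · n_eval/n_total`,
  treating every imputed reference-positive among the non-evaluable studies
  as a miss (equal-prevalence assumption).
- **Sample size for LR precision.** Smallest `n` whose expected log-scale
  CI lower bound `exp(ln LR+ − z·√(c/n))` excludes a stated value.
- **Inter-rater reliability.** For a 2-of-3-raters design, a linear mixed
  model `y_ij = μ + rater_j + b_i + e_ij` fitted by REML (subject random
  intercept, rater fixed effects); `ICC = σ²_subject/(σ²_subject+σ²_resid)`,
  with 95% bias-corrected accelerated (BCa) bootstrap CIs resampling
  patients.

## Worked example

The package ships a deterministic 1200-patient benchmark dataset whose
margins match a published chest/abdomen CT validation cohort (1087
evaluable studies, 227 with at least one VCF):

```python
>>> import vcfval as v
>>> refs, index = v.load_study_fixture()
>>> t = v.build_table(refs, index, v.ComparisonRule.ANY)
>>> (t.tp, t.fn, t.fp, t.tn)
(149, 78, 82, 778)
>>> acc = v.accuracy_summary(t)
>>> round(acc["sensitivity"].point, 2), round(acc["sensitivity"].ci_low, 2), round(acc["sensitivity"].ci_high, 2)
(0.66, 0.59, 0.72)
>>> round(acc["specificity"].point, 2)
0.9
>>> round(v.likelihood_ratios(t)["lr_pos"].point, 2)
6.88
>>> round(v.inclusive_sensitivity(t, n_total=1200, n_evaluable=1087).point, 2)
0.59
>>> v.sample_size_for_lr(0.9, 0.91, prevalence=0.15, exclude_value=8)
975
```

Reading: the detector finds 66% (95% CI 59–72%) of patients with any VCF
while calling 90% of fracture-free patients negative; a positive call
multiplies the odds of a VCF by 6.9. Counting the 113 non-evaluable studies
as misses dilutes sensitivity to 59%. Planning a new study around LR+ = 10
whose CI must exclude 8 needs 975 patients at 15% prevalence.

The same analysis runs end-to-end on synthetic or real CSV tables:

```sh
vcfval simulate --seed 5 --n 1200 --out-dir data/
vcfval report --in-dir data/ --out-dir results/ --seed 5
```

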