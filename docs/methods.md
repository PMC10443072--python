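# Methods

## Study design being modelled

A retrospective validation cohort: adults aged 50+ with existing chest or
abdomen/pelvis CT scans. Each scan is read independently by two
neuroradiologists drawn from a pool of three, who record every fractured
vertebra (17 levels, T1–T12 and L1–L5) with a Genant semiquantitative grade
(1 mild, 2 moderate, 3 severe). Any difference between the two readings —
presence, grade, or location — is resolved by a senior reader whose reading
becomes final. The index test is a patient-level binary detector that may
also return "non-evaluable". The primary analysis base is the
algorithm-evaluable subset.

## Reference standard and adjudication

`detect_disagreement` flags presence (any-fracture status differs),
location (flagged level sets differ) and grade (a shared level carries
different grades, or the locations differ) discordance. Presence
discordance implies location discordance. Two sub-cases the workflow leaves
open were decided as follows:

- A level graded by one reader and omitted by the other counts as a
  location (hence also grade) disagreement, triggering adjudication.
- On any disagreement the **senior's entire reading** becomes the
  consensus; no per-level merge is attempted, since the adjudication step
  is described only as a final diagnosis by the senior reader. Whether the
  senior reviewed only discordant levels is unknown; the whole-reading
  override is this package's choice.

`NONE` rows in readings.csv (a reader with no findings) are canonicalised
to the empty finding set before comparison.

## Contingency tables

The reference is dichotomised four ways: any fracture (max grade ≥ 1),
moderate-or-severe (≥ 2), severe (= 3), and two-or-more fractures
(count ≥ 2); everything below the threshold is reference-negative (a
mild-only patient is negative under moderate-or-severe). Non-evaluable
patients are excluded *here* — not upstream — so the inclusive
re-analysis can reuse the same references. The per-level table conditions
on the **level's own grade**, not the patient's maximum, and pairs each
level's reference-positive patients with their patient-level index result;
since the detector does not localise fractures this is a cross-level
construct, not per-level detector accuracy.

## Interval estimation

- Proportions: Clopper–Pearson exact bounds via the beta-quantile closed
  form, `Beta(α/2; k, n−k+1)` and `Beta(1−α/2; k+1, n−k)`; `k = 0` pins the
  lower bound at 0 and `k = n` the upper at 1. Exact CIs are never
  continuity-corrected.
- Likelihood ratios: the log-method (delta method on the log of the ratio
  of two independent binomial proportions), which a log-link binomial
  regression reproduces. If any 2×2 cell is zero, 0.5 is added to all four
  cells for the ratio estimates only, and the correction is recorded on the
  estimate. LR CI endpoints are validated by their structural properties
  (log-symmetry, algebraic identities with Se/Sp, bootstrap-free coverage
  logic) rather than against any single published interval, because
  published LR intervals depend on unreported modelling details.
- Inclusive sensitivity: the multiplicative form
  `Se · n_eval/n_total`, equivalent to imputing
  `(TP+FN)·(n_total−n_eval)/n_eval` additional reference-positives, all
  counted as misses; its CI is exact binomial on the rounded augmented
  denominator. The equal-prevalence assumption is untestable from the data
  and is stated, not verified.
- Sample size: closed form `n = ⌈z²c / ln²(LR+/exclude)⌉` with
  `c = 1/(p·Se) − 1/p + 1/((1−p)(1−Se_p)) − 1/(1−p)` evaluated at expected
  cell counts, plus an integer minimality check. Default planning
  prevalence is 0.15 (mid-range of published opportunistic-CT VCF
  prevalences); it is an explicit argument because validation studies
  rarely publish it.

## Reliability model

Ratings (presence 0/1, severity 0–3, count) are treated as continuous in a
linear mixed model with a random intercept per patient and fixed effects
per rater, fitted by REML. The ICC is `σ²_subject/(σ²_subject+σ²_resid)`.
A rater *variance component* is deliberately not fitted: with three raters
the rater variance is unidentifiable in practice, and the ICC definition
used involves only subject and residual variance; `rater_effects="none"`
drops the rater terms entirely.

The REML fit is a custom profiled implementation: the per-patient block
structure of the marginal covariance lets the fixed effects and residual
variance be profiled out, leaving a one-dimensional score equation in
`λ = σ²_subject/σ²_resid` that is solved by bracketed root-finding on the
analytic derivative of the REML criterion (the criterion itself is too flat
near its optimum for a minimizer to reach oracle agreement). On balanced
complete designs the result matches the classical two-way ANOVA consistency
ICC to ~1e-16, and it agrees with `statsmodels` MixedLM to that package's
convergence tolerance on unbalanced designs (both are test oracles).
Negative variance estimates truncate to zero (ICC 0); `λ ≥ 1e7` or zero
outcome variance is flagged degenerate with ICC 1.

**BCa bootstrap.** The resampling unit is the patient; a patient drawn
twice enters the resample as two distinct subjects. Bias correction `z₀`
is the normal quantile of the fraction of bootstrap statistics strictly
below the point estimate (clipped to (1/(B+1), B/(B+1))); acceleration `a`
comes from the jackknife-over-patients skewness formula; endpoints are the
adjusted percentiles. A constant statistic returns a point interval. The
default `n_boot` is 1000; the coverage simulation in the test suite uses
200 replicates of n = 300 patients with 500 bootstrap samples — sizes
chosen to keep the Monte-Carlo error of the empirical coverage near 1.5%
while the whole suite stays quick — and checks ≥ 88% empirical coverage at
a nominal 95% level.

## Synthetic cohort generator

Defaults reproduce, in expectation, the validation cohort's printed
marginals: prevalence 227/1087, highest-grade mix (90, 81, 56)/227,
multi-fracture probability 115/227, non-evaluable rate 113/1200, detector
per-grade sensitivity (42/90, 60/81, 47/56) and false-positive rate 82/860,
level weights proportional to the per-level reference-positive counts,
demographics (54% women, age bins, region mix 962/169/69) matching the
printed characteristics table.

Model structure and deliberate simplifications:

- Fracture count is 1, or 2 plus a truncated geometric (p = 0.45, chosen so
  the mean multi-fracture count ≈ 3.2 matches the ratio of total per-level
  fractures to multi-fracture patients); levels are drawn **without
  replacement** weighted by the level weights. Without-replacement draws
  mean the *pooled* level histogram is not exactly multinomial in the
  weights (high-weight levels are undersampled within multi-fracture
  patients); single-fracture levels are exactly multinomial and are what
  the goodness-of-fit test checks.
- Secondary fractures take grades from the grade mix renormalised to at
  most the patient's maximum grade.
- Reader noise: each true fracture is detected with probability
  `rater_presence_agreement` (default 0.90) and re-graded through a 4×4
  row-stochastic confusion matrix (row 0 supplies per-level reader false
  positives, default rate 0.3%). The senior has a cleaner profile;
  `perfect_senior=True` makes the adjudicated reference equal the truth
  exactly, which the parameter-recovery tests rely on.
- The detector is simulated at the patient level only, keyed to the
  patient's most severe fracture; non-evaluability is independent of
  fracture status (unknown in reality; an explicit simplification).
- The prior-VCF demographic flag (default 100/1200, reflecting the
  enrichment design) is independent of fracture truth — a passthrough
  column only.
- One root seed spawns a per-patient substream, so cohorts are
  byte-reproducible and the first k patients are invariant to `n_patients`.

What passing tests on synthetic data do **not** show: anything about image
quality, scanner heterogeneity, reader drift, or correlation between
non-evaluability and fracture burden — none of which the generator
emulates. Published reliability figures for real readers (ICC ≈ 0.68–0.86
depending on outcome) are plausibility anchors for the default noise
parameters, not reproducible targets, since raw ratings are never
published.

## Benchmark dataset

`load_study_fixture()` builds a deterministic 1200-patient dataset
satisfying every printed margin simultaneously (fracture distribution, all
four 2×2 tables, both per-level columns, 231 algorithm-positives, 113
non-evaluable). Differencing the cumulative severity tables fixes the
(grade × algorithm result) joint; the two-or-more table fixes
(multiplicity × algorithm result); singles are assigned mild-first; levels
are dealt greedily from the thoracolumbar junction outward, anchors first,
remaining slots to the least-loaded multi-fracture patient not already
occupying the level. Any dataset consistent with the margins would yield
identical downstream statistics; the construction is re-verified on every
load and raises naming the violated constraint if the tables are edited
inconsistently. Non-evaluable patients are given fracture-free references —
no printed margin constrains their truth.

## Numerical conventions

- Printed-precision comparisons round half-away-from-zero (2 dp for
  proportions, integer percent for rates).
- Undefined statistics (zero denominator margin) are returned as missing by
  default and raise, naming the zero margin, in strict mode.
- Pipeline artifacts are byte-reproducible: no timestamps, fixed float
  formatting, seeded bootstraps; provenance records the seed, version and
  input/config hashes.

## Known limitations

- The LR CI formula is one defensible reading of "log-linear regression"
  interval estimation; alternatives (profile likelihood, different
  covariance structures) give slightly different endpoints.
- The inclusive-sensitivity imputation is the simplest (multiplicative)
  form; informative non-evaluability would bias it in either direction.
- Binary and ordinal outcomes are analysed in a linear mixed model (as is
  common in reader-agreement practice); a logistic ICC is out of scope.
- The generator's rater noise is i.i.d. across vertebrae and patients; real
  readers err systematically near grade boundaries.
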