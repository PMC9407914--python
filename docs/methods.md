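# Methods

## The statistic

Subjects are cross-tabulated by reclassification direction (down / none /
up, from predicted risks under a base and an extended model) against the
binary outcome, giving observed counts `a..f` (rows direction, columns
disease-free / diseased). Expected counts are the usual independence
products, row marginal × column marginal / n, which conserve both margins.
Because no subject can occupy the "hidden" middle column that squares the
table, Cohen's kappa on the augmented 3×3 table reduces exactly to

    κ = (O − E) / (n − E),  O = a_O + f_O,  E = a_E + f_E,

and the excess x = O − E equals both per-column decompositions
(a_O − e_O) − (a_E − e_E) and (f_O − b_O) − (f_E − b_E); the package
asserts this identity to 1e-9·n. κ is computed from unrounded expected
counts; rounding (half away from zero, the convention clinicians expect)
applies only to the reported person count x, and the raw value is always
retained. When n = E the statistic is undefined and is reported as
not-available (NaN), never as 0 — matching how zero-movement rows are
reported (estimate 0, p-value NA).

## Direction rules

* **continuous** — any strict change counts. Ties are exact floating
  equality; an optional tolerance `tie_tol` (default 0) is exposed because
  refitting can leave sub-ulp noise on risks.
* **unit(δ)** — only |Δrisk| *strictly greater* than δ counts (default
  δ = 0.01, i.e. a 1% step); δ is arbitrary, so multi-unit variants (e.g.
  δ = 1/3) need no extra code.
* **categorical(c₁ < c₂ < …)** — direction is the sign of the category
  change, where the category of p is the number of cut-points strictly
  below p; a risk exactly at a cut-point therefore sits in the lower
  category. The boundary convention is a deliberate, documented choice —
  any fixed convention works, but it must be fixed. The study uses the
  observed event rate as the single cut-off.

## Inference

No canonical variance is attached to the reclassification κ, so the
package adopts the community-standard estimators and backs them with a
bootstrap:

* κ: the Fleiss–Cohen–Everitt large-sample variance on the augmented
  table (Wald CI clipped to [−1, 1]); the test of κ = 0 uses the
  corresponding null-hypothesis variance (score-type z test).
* NRI: the binomial events/non-events decomposition
  `var = [p_up|D + p_down|D − (p_up|D − p_down|D)²]/n_D + (analogue)/n_ND`,
  per component and total.
* bootstrap (reference method, default B = 2000, seed recorded in the
  result): subjects are resampled with replacement stratified by outcome.
  Since a subject is fully characterised by (direction, outcome), this is
  implemented as two multinomial draws over the direction distribution of
  each outcome column, so it runs from the table alone. Percentile CIs;
  the p-value is twice the smaller tail fraction of the resampled statistic
  around zero.

Tests are two-sided at α = 0.05 throughout. Any zero denominator yields
NA, never 0.

## Model evaluation

Logistic fits are maximum likelihood (statsmodels Newton, BFGS fallback);
perfect separation is flagged (`converged=False`, a warning) rather than
raised, since a saturating fit still defines risks. Odds ratios carry Wald
CIs; nested models are compared by the likelihood-ratio χ² test; model fit
by Nagelkerke R² (Cox–Snell rescaled to a unit maximum). AUC is the
Mann–Whitney statistic with midrank ties; the paired AUC-change test is
DeLong-style, with variances and covariance from placement values. The
forward-stepwise helper enters covariates by smallest LR p-value below
α = 0.05 (an optional removal pass mirrors the usual stepwise variant but
is off by default).

## Synthetic cohort

The generator emulates a population CVD-screening cohort: n = 3971,
target outcome prevalence 1765/3971 ≈ 0.4444, five categorical lifestyle
covariates (BMI, residence, marital status, income, daily activity), two
informative candidate markers (a protective education gradient and a strong
binary score, univariable OR ≈ 22.7), and six noise markers drawn
independently of the outcome from uniform(0, 100), normal(0, 1),
Poisson(4), exponential(rate 1), Bernoulli(0.1) and Bernoulli(0.5).

Covariates are sampled *independently* from their marginal frequencies —
only marginals are specified, so no real-world correlation structure is
emulated; this is the generator's main idealisation. Outcomes follow
Bernoulli(expit(β₀ + Ση)) on the conditional log-odds in
`src/reclasskappa/data/default_config.yaml` (version 1). Those defaults
were calibrated once by Monte-Carlo fixed-point iteration so the
*univariable* (marginal) odds ratios match the intended targets —
conditional effects exceed marginal ones because logistic models are
non-collapsible (e.g. the score's conditional log-odds is 3.417 for a
marginal OR of 22.7). With these defaults the fitted base model
(BMI + income + activity) lands at AUC ≈ 0.59 without further tuning.

β₀ is calibrated by Brent root-finding on the Monte-Carlo mean risk
(default 200 000 draws, tolerance 1e-4 on prevalence); it is a property of
the outcome model only, so its seed derives from a hash of the covariate
effects and target prevalence — adding a noise-marker spec or changing n
perturbs nothing else. Every column draws from its own RNG substream keyed
by (seed, column name), so cohorts are reproducible column-by-column.

Because covariates are independent and effects are idealised, passing
tests demonstrate the *statistical machinery* (calibration of tests,
chance correction, detection power), not the epidemiology of any real
cohort: real data add covariate correlation, measurement error and
calibration drift that the generator deliberately omits.

## Study runner and problem sizes

`run_study` draws a cohort, builds the base model (forward stepwise by
default), extends it one marker at a time, and reports the joint Wald test
of the added term, the LR test, AUCs with the DeLong change test, and
x / κ / NRI with CIs under the three rules (categorical cut-off = observed
event rate). Reports are byte-identical for identical config + seed; the
optional metadata sidecar (with a timestamp) is kept out of the CSV for
that reason.

Default problem sizes were chosen to keep the full check suite comfortably
interactive while leaving Monte-Carlo error well below the asserted
margins: the type-I-error study uses 2000 replicates at n = 1000 (binomial
SE ≈ 0.0033 around 0.05, base model income + activity — covariates without
rare categories, so small-n fits stay regular); signal detection uses 50
replicates at the full n = 3971; prevalence recovery uses 10⁶ draws.

## Known limitations and observed behaviour

* The categorical (event-rate) κ z-test is *conservative* in the null
  study at n = 1000: measured type-I error ≈ 0.023 at nominal 0.05
  (2000 replicates), versus ≈ 0.056 (continuous) and ≈ 0.053 (unit).
  With a weak base model, few subjects cross the cut-off when a noise
  marker is added; about a fifth of replicates show no crossings at all
  (reported NA, counted as non-rejections) and the rest give sparse,
  discrete tables. This under-rejection is one face of the variant's
  robustness to noise markers; users should expect reduced power at
  moderate n, not inflated false positives.
* Asymptotic κ/NRI variances are large-sample forms; for small tables the
  seeded stratified bootstrap is the safer reference.
* The generator does not emulate miscalibration between models, so
  sensitivity of κ to poorly calibrated risk (a known concern for
  reclassification measures) is out of scope here.
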