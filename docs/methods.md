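# Methods

## Setting and notation

The unit of analysis is a cohort of ER+/HER2− breast-cancer patients with a
metastatic sentinel-node (SN) biopsy, every one of whom also underwent
completion axillary lymph node dissection (ALND), so the non-sentinel-node
(NSN) ground truth is known for all. Each patient carries

- the SN metastasis category: isolated tumor cells (ITC, pN0(i+), ≤ 0.2 mm),
  micrometastasis (pN1(mic), ≤ 2 mm) or macrometastasis (pN1, > 2 mm);
- the MSKCC nomogram score *p* ∈ [0, 1], the predicted probability of NSN
  involvement (the nomogram is an external calculator; scores are inputs
  here, never recomputed);
- the count of metastatic non-sentinel nodes found at completion ALND, whose
  positivity (count > 0) is the outcome every statistic is judged against.

A threshold *t* partitions the cohort into LOW (score ≤ *t*) and HIGH
(score > *t*). Ties at the threshold always go LOW — with the published
cross-tabulation at *t* = 0.3 this is the only reading under which the
low-risk group totals 536 (171 ITC + 274 micro + 91 macro), so the "≤"
convention is used consistently in stratification, classification and
costing.

## Classification metrics

Truth = NSN-positive, prediction = score > *t*. Besides sensitivity
tp/(tp+fn), specificity tn/(tn+fp), predictive values and accuracy, the
package reports `fn_rate_total` = FN/N and `fp_rate_total` = FP/N —
proportions of the *whole cohort*, which is the convention behind the
headline 6.4% (66/1036) and 28.9% (299/1036). Both conventions are exposed;
the whole-cohort one carries the headline name because it is what a clinic
trades off when choosing *t*. Ratios with a zero denominator are returned as
`None`, never coerced to 0. Displayed percentages round half away from zero
to one decimal.

## Validation

**Discrimination.** AUC is the Mann–Whitney probability that a random
NSN-positive patient outscores a random NSN-negative one, ties counting ½
(computed via scikit-learn; the test suite re-derives it by brute-force
pairwise enumeration). Confidence intervals: Hanley–McNeil (default; normal
approximation with the classic variance), DeLong (midrank placements), or a
percentile bootstrap over patients (2000 replicates by default). The default
is Hanley–McNeil because the method used for the original interval is not
documented; all three are available.

**Calibration.** "Calibration plot by linear regression" is implemented as
logistic recalibration — fit logit P(y=1) = α + β·logit(p) by maximum
likelihood — because the null hypothesis (α, β) = (0, 1) with a 2-df
likelihood-ratio chi-square is only well defined in that framework: the
null model is nested in the 2-parameter family and its log-likelihood is the
Bernoulli log-likelihood at p itself. Scores at exactly 0 or 1 are clamped
by ε = 10⁻⁶ before the logit. A reliability curve over equal-count bins
(deciles by default) and the OLS line through it are also produced, so the
probability-scale reading of "regression" remains available for plots.

## Decision-tree cost model

Unit costs (euros, all-inclusive tariffs): SN biopsy alone 2971; SN biopsy +
immediate ALND in the same procedure 4050; SN biopsy + delayed ALND in a
second procedure 5335. These include the intraoperative frozen-section exam;
in the no-frozen-section strategy its average cost of 54 € is subtracted
(2917 and 5281). Counts being integers, totals are exact integer euros.

The management policy sends macrometastases to completion ALND
unconditionally and smaller deposits only when score > *t*. The
unconditional-macrometastasis rule is central: with it, the no-frozen-section
savings at *t* = 0.3 are exactly 445 × (5281 − 2917) = 1,051,980 € and the
avoided-ALND fraction 445/1036 ≈ 43%; without it neither number is
reproducible.

Frozen-section detection is Bernoulli per patient with type-specific
probabilities (macro 0.90, micro 0.11, ITC 0.0), independent of the score —
the score is only computed post-operatively, so a detected patient costs
4050 € regardless of later classification. Analytic branch counts are
expected values (rate × cell count). With `Rounding.NEAREST`, detected
totals per metastasis type are rounded half-up to whole patients
(508 macro + 33 micro = 541 detected, 495 undetected), which makes the
frozen-section-vs-no-frozen-section saving under the all-ALND comparator an
exact 639,241 €. For the mixed branch (undetected, split by ALND
indication) the not-indicated branch is rounded half-up and the indicated
branch takes the remainder, keeping the partition exact. `Rounding.NONE`
keeps fractional expectations and is the form the Monte-Carlo oracle must
agree with.

The Monte-Carlo simulation re-runs the same tree per patient per replicate
with Bernoulli detections; its mean total must sit within 3 standard errors
of the analytic `Rounding.NONE` total for every strategy. The
no-frozen-section strategy has no randomness, so its simulated variance is
zero by construction.

**Savings identity.** Versus the all-ALND comparator, no-frozen-section
savings equal (number of avoided dissections) × (5281 − 2917) = avoided ×
2364 € at any threshold; they are therefore non-decreasing in *t*, and
raising *t* from 0.3 past every small-deposit score adds the 27 remaining
above-threshold non-macro patients, worth 27 × 2364 = 63,828 €.

Not modelled: discounting, QALYs/ICERs, morbidity costs, currency
conversion, probabilistic sensitivity analysis beyond the Monte-Carlo check.
Three published intermediate figures (979,775 €, 1,619,016 €, 567,036 € and
the 59,100 € sweep maximum with frozen section) could not be reproduced
exactly under any rounding scheme we tried (closest reconstructions differ
by ≤ 0.2%; the intermediate arithmetic behind them is not stated); the tool
reports its own figures for those comparisons and no test asserts them.

## Synthetic cohort generator

The generator emulates the published study conditions, which pin:

- SN-type marginals (173, 299, 564)/1036;
- the mass of each type's score distribution below 0.3
  (171/173, 274/299, 91/564);
- group NSN-positivity rates at *t* = 0.3: 66/536 (LOW) and 201/500 (HIGH);
- overall score spread: median 0.3, 90% below 0.6.

Scores are per-type Beta(a, b). Two CDF anchors identify each shape pair:
the published mass below 0.3, and a second anchor at 0.6 — 0.999 for ITC and
0.99 for micrometastases (small deposits essentially never score high), with
the macrometastasis anchor then solved from the overall 90%-below-0.6
constraint (≈ 0.822). The pair is found by least-squares root-finding in
log-shape space; residuals are checked below 10⁻⁶. The published tables
under-determine the full distributions, so this is a modelling choice, made
once; the resulting overall median sits near 0.3 by construction
(Σ πᵢ·CDFᵢ(0.3) = 536/1036 ≈ 0.517).

NSN outcomes: `GROUP_RATES` (default) draws Bernoulli with the group rate —
the tables only constrain group-level positivity; `CALIBRATED` sets
P(NSN+ | p) = p, a perfectly calibrated truth used to exercise the LR test
under its null (its empirical type-I error at 5% must land in (0.02, 0.10)
over 200 replicates of n = 10⁴). Positive-node counts are drawn from the
published per-group count breakdown (">3" stored as 4). Optional covariates
(age, tumor type/size, pT, grade, LVI, SN count) follow the published
per-group frequencies, uniform within bins; they feed summaries only and
never influence classification or costs. The same seed yields a bit-identical
cohort (`numpy.random.default_rng`).

What the generator does *not* emulate: the joint dependence of covariates
and score beyond risk-group conditioning, any within-type association
between score and NSN outcome under `GROUP_RATES`, and the true (unpublished)
score histogram. Tests passing on synthetic cohorts therefore show the
pipeline's arithmetic and statistical machinery are right under the
published margins — not that the nomogram performs identically on new
patient-level data; in particular the synthetic AUC (≈ 0.67 under group
rates) has no reason to match an AUC estimated on real scores.

`reference_cohort()` sidesteps sampling entirely: a deterministic cohort of
1036 patients whose stratification at 0.3 reproduces the published
cross-tabulation exactly, with representative scores 0.25/0.45 on either
side of the threshold (only the side matters downstream) and NSN-positive
status assigned deterministically from the macrometastasis end of each
group. All exact headline checks run on it.

## Problem sizes and numerical choices

Deterministic checks use the 1036-patient reference cohort and complete in
milliseconds. Stochastic checks use n = 10⁴ replicates for the Monte-Carlo
oracle, 200 × n = 10⁴ replicates for the LR-test type-I error, and n = 10⁵
for generator-calibration recovery — sizes at which 3-standard-error bands
are decisive while the whole suite stays fast. Bootstrap CIs default to 2000
replicates. CSV dialect: comma-separated UTF-8, header required, `NA` for
missing optional values, booleans 0/1; pathology synonyms (pN0(i+),
pN1(mic), pN1) are accepted for the metastasis type on read.
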