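# axicost

Medico-economic analysis of nomogram-guided axillary management in
sentinel-node-positive, ER+/HER2− breast cancer.

## The problem

After a metastatic sentinel-node (SN) biopsy, completion axillary lymph node
dissection (ALND) is still standard care in many countries, yet 40–70% of
these patients have no further nodal disease — the dissection adds morbidity
without changing management. The MSKCC non-sentinel-node nomogram assigns
each SN-positive patient a probability *p* of non-sentinel-node (NSN)
involvement. A clinic can adopt a threshold policy: patients with a
macrometastatic SN always undergo completion ALND; patients with
micrometastases or isolated tumor cells (ITC) undergo it only if *p* exceeds
a threshold *t*.

`axicost` is for biostatisticians and health-economics analysts evaluating
such a policy. It provides:

- **Cohort model** — typed patient records (SN metastasis category, nomogram
  score, NSN outcome, covariates), strict CSV round-tripping, descriptive
  summaries, and stratification into low/high risk at any threshold
  (LOW ⟺ score ≤ *t*).
- **Threshold classification** — confusion matrices with truth = NSN
  positivity and prediction = score > *t*; sensitivity, specificity,
  predictive values and the whole-cohort rates FN/N and FP/N; sweeps over
  *t* = 0.1 … 0.9.
- **Nomogram validation** — AUC (Mann–Whitney, ties ½) with Hanley–McNeil,
  DeLong or bootstrap confidence intervals, and logistic recalibration
  logit P(y=1) = α + β·logit(p) with a 2-df likelihood-ratio test of the
  perfect-calibration null (α, β) = (0, 1), plus an equal-count reliability
  curve.
- **Cost model** — a decision tree comparing care strategies with and without
  an intraoperative frozen-section exam of the SN. Frozen section detects
  90% of macrometastases, 11% of micrometastases and 0% of ITC
  intraoperatively; detected patients get an immediate ALND (4050 €),
  undetected ALND-indicated patients a delayed ALND (5335 €), the rest keep
  the SN biopsy alone (2971 €). Without frozen section, tariffs drop by its
  54 € cost (5281 €/2917 €). Expected branch counts, totals, savings versus
  an all-ALND comparator, threshold cost sweeps, and a per-patient
  Monte-Carlo simulation as a stochastic cross-check.
- **Synthetic cohorts** — a generator calibrated to the published marginal
  and threshold-stratified distributions of a 1036-patient cohort (per-type
  Beta score laws, group-wise or perfectly calibrated NSN outcomes), and a
  deterministic `reference_cohort()` that reproduces the published
  cross-tabulation at *t* = 0.3 cell for cell.

## Worked example

```python
import axicost as ax

ref = ax.reference_cohort()            # deterministic 1036-patient cohort
cm = ax.classify(ref, 0.3)
ms = ax.metrics(cm)
print(f"TN={cm.tn} FN={cm.fn} TP={cm.tp} FP={cm.fp}")
print(f"sensitivity={ms.sensitivity:.1%} specificity={ms.specificity:.1%} "
      f"FN/N={ms.fn_rate_total:.1%} accuracy={ms.accuracy:.1%}")

sc = ax.stratify(ref, 0.3)
policy = ax.AlndPolicy(0.3)
nomo = ax.strategy_cost(sc, policy, strategy=ax.Strategy.NO_FS,
                        comparator=ax.Comparator.NOMOGRAM)
all_alnd = ax.strategy_cost(sc, policy, strategy=ax.Strategy.NO_FS,
                            comparator=ax.Comparator.ALL_ALND)
print(f"nomogram policy: {nomo.total:,.0f} EUR  all-ALND: {all_alnd.total:,.0f} EUR  "
      f"saved: {ax.savings(nomo, all_alnd):,.0f} EUR")
```

prints

```
TN=470 FN=66 TP=201 FP=299
sensitivity=75.3% specificity=61.1% FN/N=6.4% accuracy=64.8%
nomogram policy: 4,419,136 EUR  all-ALND: 5,471,116 EUR  saved: 1,051,980 EUR
```

Read: at threshold 0.3 the policy would omit 445 of 1036 dissections (43%);
66 patients (6.4% of the cohort) with positive non-sentinel nodes would be
spared a dissection they'd have needed, and the no-frozen-section strategy
saves 1,051,980 € over dissecting everyone.

The same pipeline is scriptable from the shell:

```bash
axicost simulate --n 1036 --seed 42 --out cohort.csv
axicost classify cohort.csv --threshold 0.3
axicost report --seed 42 --outdir report/     # summary, metrics, costs, sweeps
```

## Layout

| Module | Contents |
| --- | --- |
| `axicost.cohort` | domain types, CSV I/O, stratification, summaries |
| `axicost.simulate` | calibrated generator and the deterministic reference cohort |
| `axicost.classify` | confusion matrices, metric sets, threshold sweep |
| `axicost.validation` | ROC/AUC with CIs, logistic recalibration + LR test |
| `axicost.costs` | decision-tree strategy costs, savings, sweep, Monte-Carlo |
| `axicost.report`, `axicost.cli` | report bundle and the `axicost` command |

See `docs/methods.md` for the model, its assumptions and the numerical
choices.
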