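"""Combined report: every headline table for a cohort at one threshold.

The report layer only orchestrates and serializes — every number it writes is
produced by the cohort, classification, validation and cost modules, and the
same run configuration always yields byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .classify import DEFAULT_THRESHOLD_GRID, classify, metrics, sweep
from .cohort import Cohort, read_cohort, stratify, summarize
from .costs import (
    AlndPolicy,
    Comparator,
    CostParameters,
    DetectionRates,
    Rounding,
    Strategy,
    cost_sweep,
    savings,
    strategy_cost,
)
from .simulate import GeneratorParams, default_params, generate
from .validation import CIMethod, calibration, roc

__all__ = ["RunConfig", "run_report"]

log = logging.getLogger("axicost")


@dataclass
class RunConfig:
    """Inputs of one report run: a cohort (CSV path or generator parameters),
    the threshold, and the knobs of the downstream stages."""

    input_csv: Optional[str] = None
    generator: Optional[GeneratorParams] = None
    threshold: float = 0.3
    thresholds: Sequence[float] = DEFAULT_THRESHOLD_GRID
    rounding: Rounding = Rounding.NEAREST
    ci_method: CIMethod = CIMethod.HANLEY
    n_bins: int = 10
    seed: int = 0
    costs: CostParameters = field(default_factory=CostParameters)
    detection: DetectionRates = field(default_factory=DetectionRates)
    outdir: str = "axicost_report"

    def __post_init__(self) -> None:
        for t in [self.threshold, *self.thresholds]:
            if not (0.0 < t < 1.0):
                raise ValueError(f"threshold {t} outside (0, 1)")


def _load_cohort(config: RunConfig) -> Cohort:
    if config.input_csv is not None:
        return read_cohort(config.input_csv)
    params = config.generator or default_params(seed=config.seed)
    return generate(params)


def _json_dump(obj: object, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_report(config: RunConfig) -> dict[str, Path]:
    """Run every stage on one cohort and write the report bundle.

    Emits ``summary.csv``, ``stratified.csv``, ``metrics.json``,
    ``validation.json``, ``costs.json``, ``sweep_metrics.csv`` and
    ``sweep_costs.csv`` into ``config.outdir`` and returns their paths.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = _load_cohort(config)
    log.info(
        "axicost %s: report on %d patients (threshold %.2f, seed %d)",
        __version__, len(cohort), config.threshold, config.seed,
    )

    paths: dict[str, Path] = {}

    df = summarize(cohort)
    paths["summary"] = outdir / "summary.csv"
    df.to_csv(paths["summary"], index=False, na_rep="NA")

    sc = stratify(cohort, config.threshold)
    paths["stratified"] = outdir / "stratified.csv"
    sc.to_dataframe().to_csv(paths["stratified"], index=False)

    cm = classify(cohort, config.threshold)
    ms = metrics(cm)
    paths["metrics"] = outdir / "metrics.json"
    _json_dump(
        {
            "threshold": config.threshold,
            "n": cm.n,
            "tn": cm.tn,
            "fn": cm.fn,
            "tp": cm.tp,
            "fp": cm.fp,
            "per_type": {t.value: list(cells) for t, cells in cm.per_type.items()},
            **ms.as_dict(),
        },
        paths["metrics"],
    )

    scores, labels = cohort.scores(), cohort.labels()
    validation: dict[str, object]
    try:
        r = roc(scores, labels, ci_method=config.ci_method, seed=config.seed)
        c = calibration(scores, labels, n_bins=config.n_bins)
        validation = {
            "auc": r.auc,
            "auc_ci": [r.ci_low, r.ci_high],
            "ci_method": r.ci_method.value,
            "alpha": c.intercept_alpha,
            "beta": c.slope_beta,
            "lr_chi2": c.lr_chi2,
            "lr_df": c.lr_df,
            "lr_pvalue": c.lr_pvalue,
            "binned_curve": [list(b) for b in c.binned_curve],
        }
    except ValueError as exc:  # degenerate cohorts (e.g. unique score)
        validation = {"error": str(exc)}
    paths["validation"] = outdir / "validation.json"
    _json_dump(validation, paths["validation"])

    policy = AlndPolicy(threshold=config.threshold)
    cost_block: dict[str, object] = {"threshold": config.threshold, "rounding": config.rounding.value}
    for strat in Strategy:
        nomo = strategy_cost(sc, policy, config.costs, config.detection, strat, Comparator.NOMOGRAM, config.rounding)
        ref = strategy_cost(sc, policy, config.costs, config.detection, strat, Comparator.ALL_ALND, config.rounding)
        cost_block[strat.value] = {
            "nomogram": {"branches": dict(nomo.branch_counts), "total": nomo.total},
            "all_alnd": {"branches": dict(ref.branch_counts), "total": ref.total},
            "savings_vs_all_alnd": savings(nomo, ref),
        }
    paths["costs"] = outdir / "costs.json"
    _json_dump(cost_block, paths["costs"])

    paths["sweep_metrics"] = outdir / "sweep_metrics.csv"
    sweep(cohort, config.thresholds).to_csv(paths["sweep_metrics"], index=False)
    paths["sweep_costs"] = outdir / "sweep_costs.csv"
    cost_sweep(cohort, config.thresholds, config.costs, config.detection, config.rounding).to_csv(
        paths["sweep_costs"], index=False
    )
    return paths
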