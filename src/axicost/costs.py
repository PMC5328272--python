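"""Decision-tree cost model for axillary management guided by the nomogram.

Two care strategies are compared for a cohort of sentinel-node (SN) positive
patients, each against two comparators:

* **FS** — an intraoperative frozen-section exam of the SN is performed.
  Patients whose metastasis is detected intraoperatively get an immediate
  completion axillary dissection (ALND) in the same procedure.  Detection
  probabilities depend only on the metastasis type (macrometastases 90%,
  micrometastases 11%, isolated tumor cells 0%).  Undetected patients either
  return for a delayed ALND or keep the SN biopsy alone, according to the
  management policy.
* **NO_FS** — no frozen-section exam; every ALND-indicated patient has a
  delayed ALND.  Unit costs drop by the frozen-section cost (54 euros).

The management policy under study sends macrometastases to completion ALND
always, and smaller deposits only when the nomogram score exceeds the
threshold; the comparator ALL_ALND dissects everyone.  Expected branch counts
are products of cell counts and detection rates; with NEAREST rounding the
detected totals per metastasis type are rounded half-up to whole patients.
A per-patient Monte-Carlo simulation of the same tree serves as an
independent stochastic check of the analytic expectations.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, NSNStatus, RiskGroup, SNType, stratify

__all__ = [
    "CostParameters",
    "DetectionRates",
    "AlndPolicy",
    "Strategy",
    "Comparator",
    "Rounding",
    "StrategyCost",
    "expected_counts",
    "strategy_cost",
    "savings",
    "cost_sweep",
    "monte_carlo_cost",
]


class Strategy(str, enum.Enum):
    FS = "fs"          # with intraoperative frozen-section exam
    NO_FS = "no_fs"    # without


class Comparator(str, enum.Enum):
    NOMOGRAM = "nomogram"   # ALND iff macrometastasis or score > threshold
    ALL_ALND = "all_alnd"   # every SN-positive patient dissected


class Rounding(str, enum.Enum):
    NEAREST = "nearest"  # detected counts rounded half-up to whole patients
    NONE = "none"        # fractional expected counts


@dataclass(frozen=True)
class CostParameters:
    """Procedure costs in euros.

    The three base tariffs include the frozen-section exam; the ``*_no_fs``
    properties subtract its average cost for the strategy without the exam.
    """

    sn_only: float = 2971.0
    sn_immediate_alnd: float = 4050.0
    sn_delayed_alnd: float = 5335.0
    frozen_section: float = 54.0

    def __post_init__(self) -> None:
        if min(self.sn_only, self.sn_immediate_alnd, self.sn_delayed_alnd, self.frozen_section) <= 0:
            raise ValueError("all costs must be positive")

    @property
    def sn_only_no_fs(self) -> float:
        return self.sn_only - self.frozen_section  # 2917 with defaults

    @property
    def sn_delayed_alnd_no_fs(self) -> float:
        return self.sn_delayed_alnd - self.frozen_section  # 5281 with defaults


@dataclass(frozen=True)
class DetectionRates:
    """Probability that the frozen-section exam detects the SN metastasis
    intraoperatively, by metastasis type."""

    itc: float = 0.0
    micro: float = 0.11
    macro: float = 0.90

    def __post_init__(self) -> None:
        for r in (self.itc, self.micro, self.macro):
            if not (0.0 <= r <= 1.0):
                raise ValueError("detection rates must lie in [0, 1]")

    def rate(self, sn_type: SNType) -> float:
        return {SNType.ITC: self.itc, SNType.MICRO: self.micro, SNType.MACRO: self.macro}[sn_type]


@dataclass(frozen=True)
class AlndPolicy:
    """Completion-ALND indication rule.

    Macrometastases always undergo completion ALND; micrometastases and
    isolated tumor cells only when the nomogram score exceeds the threshold.
    """

    threshold: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie strictly in (0, 1)")

    def indicated(self, sn_type: SNType, score: float) -> bool:
        return sn_type is SNType.MACRO or score > self.threshold

    def indicated_cell(self, risk: RiskGroup, sn_type: SNType) -> bool:
        return sn_type is SNType.MACRO or risk is RiskGroup.HIGH


@dataclass(frozen=True)
class StrategyCost:
    """Expected branch counts and total cost of one strategy/comparator pair."""

    strategy: Strategy
    comparator: Comparator
    threshold: float
    rounding: Rounding
    branch_counts: Mapping[str, float]   # branch name -> expected patients
    branch_costs: Mapping[str, float]    # branch name -> unit cost (euros)
    total: float                         # sum of count x unit cost

    @property
    def n(self) -> float:
        return sum(self.branch_counts.values())


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def expected_counts(
    sc, dr: DetectionRates, rounding: Rounding = Rounding.NEAREST
) -> dict[str, dict[SNType, float]]:
    """Expected detected/undetected patients per SN metastasis type.

    Detected = rate x type count (summed over risk groups); with NEAREST the
    per-type detected totals are rounded half-up, undetected is the remainder.
    """
    out: dict[str, dict[SNType, float]] = {"detected": {}, "undetected": {}}
    for t in SNType:
        total = sc.type_total(t)
        det = dr.rate(t) * total
        if rounding is Rounding.NEAREST:
            det = _round_half_up(det)
        out["detected"][t] = det
        out["undetected"][t] = total - det
    return out


def strategy_cost(
    sc,
    policy: AlndPolicy,
    cp: CostParameters = CostParameters(),
    dr: DetectionRates = DetectionRates(),
    strategy: Strategy = Strategy.NO_FS,
    comparator: Comparator = Comparator.NOMOGRAM,
    rounding: Rounding = Rounding.NEAREST,
) -> StrategyCost:
    """Total expected cost of caring for the stratified cohort under one
    strategy/comparator pair, following the decision tree branch by branch."""
    strategy = Strategy(strategy)
    comparator = Comparator(comparator)
    rounding = Rounding(rounding)
    n = sc.total

    counts: dict[str, float]
    costs: dict[str, float]
    if strategy is Strategy.NO_FS:
        if comparator is Comparator.ALL_ALND:
            counts = {"delayed_alnd": float(n)}
            costs = {"delayed_alnd": cp.sn_delayed_alnd_no_fs}
        else:
            indicated = sum(
                sc.group_type(r, t)
                for r in RiskGroup
                for t in SNType
                if policy.indicated_cell(r, t)
            )
            counts = {"delayed_alnd": float(indicated), "sn_only": float(n - indicated)}
            costs = {"delayed_alnd": cp.sn_delayed_alnd_no_fs, "sn_only": cp.sn_only_no_fs}
    else:  # FS
        ec = expected_counts(sc, dr, rounding)
        detected = sum(ec["detected"].values())
        if comparator is Comparator.ALL_ALND:
            counts = {"immediate_alnd": float(detected), "delayed_alnd": float(n - detected)}
            costs = {
                "immediate_alnd": cp.sn_immediate_alnd,
                "delayed_alnd": cp.sn_delayed_alnd,
            }
        else:
            # Undetected patients split by ALND indication.  Detection is
            # uniform within a type, so undetected LOW non-macro patients are
            # the LOW share of each type's undetected remainder.
            not_indicated = 0.0
            for t in (SNType.ITC, SNType.MICRO):
                total_t = sc.type_total(t)
                if total_t == 0:
                    continue
                undet_frac = ec["undetected"][t] / total_t
                not_indicated += undet_frac * sc.group_type(RiskGroup.LOW, t)
            if rounding is Rounding.NEAREST:
                not_indicated = _round_half_up(not_indicated)
            counts = {
                "immediate_alnd": float(detected),
                "sn_only": float(not_indicated),
                "delayed_alnd": float(n - detected - not_indicated),
            }
            costs = {
                "immediate_alnd": cp.sn_immediate_alnd,
                "sn_only": cp.sn_only,
                "delayed_alnd": cp.sn_delayed_alnd,
            }

    total = sum(counts[b] * costs[b] for b in counts)
    # integral counts give exact integral euro totals
    if all(float(c).is_integer() for c in counts.values()):
        total = float(round(total))
    return StrategyCost(
        strategy=strategy,
        comparator=comparator,
        threshold=policy.threshold,
        rounding=rounding,
        branch_counts=dict(counts),
        branch_costs=dict(costs),
        total=total,
    )


def savings(a: StrategyCost, b: StrategyCost) -> float:
    """Euros saved by strategy ``a`` relative to ``b`` (positive when ``a`` is
    cheaper).  Both must cost the same cohort."""
    if abs(a.n - b.n) > 0.5:
        raise ValueError("strategies cost different cohort sizes")
    return b.total - a.total


def cost_sweep(
    cohort: Cohort,
    thresholds: Sequence[float] = tuple(round(0.1 * k, 1) for k in range(1, 10)),
    cp: CostParameters = CostParameters(),
    dr: DetectionRates = DetectionRates(),
    rounding: Rounding = Rounding.NEAREST,
) -> pd.DataFrame:
    """Total cost of both strategies across thresholds, with savings versus
    the matching all-ALND comparator.  Stratification is recomputed per
    threshold."""
    rows = []
    for t in thresholds:
        sc = stratify(cohort, t)
        policy = AlndPolicy(threshold=t)
        for strat in Strategy:
            nomo = strategy_cost(sc, policy, cp, dr, strat, Comparator.NOMOGRAM, rounding)
            ref = strategy_cost(sc, policy, cp, dr, strat, Comparator.ALL_ALND, rounding)
            rows.append(
                {
                    "threshold": t,
                    "strategy": strat.value,
                    "total_nomogram": nomo.total,
                    "total_all_alnd": ref.total,
                    "savings_vs_all_alnd": savings(nomo, ref),
                }
            )
    return pd.DataFrame(rows)


def monte_carlo_cost(
    cohort: Cohort,
    policy: AlndPolicy,
    cp: CostParameters = CostParameters(),
    dr: DetectionRates = DetectionRates(),
    strategy: Strategy = Strategy.FS,
    n_reps: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Per-patient Monte-Carlo simulation of the decision tree.

    Each replicate draws every patient's intraoperative detection as a
    Bernoulli with the type-specific rate and assigns the pathway cost.
    Returns (mean total, standard error of the mean) over replicates — the
    stochastic oracle for the analytic expected-count model (NONE rounding).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    strategy = Strategy(strategy)
    rng = np.random.default_rng(seed)
    rates = np.array([dr.rate(p.sn_type) for p in cohort])
    indicated = np.array([policy.indicated(p.sn_type, p.mskcc_score) for p in cohort])
    n = len(cohort)

    if strategy is Strategy.NO_FS:
        total = float(
            indicated.sum() * cp.sn_delayed_alnd_no_fs
            + (n - indicated.sum()) * cp.sn_only_no_fs
        )
        return total, 0.0

    undetected_cost = np.where(indicated, cp.sn_delayed_alnd, cp.sn_only)
    totals = np.empty(n_reps)
    for r in range(n_reps):
        detected = rng.random(n) < rates
        totals[r] = np.where(detected, cp.sn_immediate_alnd, undetected_cost).sum()
    se = float(totals.std(ddof=1) / math.sqrt(n_reps)) if n_reps > 1 else 0.0
    return float(totals.mean()), se
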