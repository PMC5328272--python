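"""Patient-level cohort model for sentinel-node-positive ER+/HER2- breast cancer.

A cohort is an ordered collection of SN-positive patients, each carrying the
type of sentinel-node metastasis (isolated tumor cells, micrometastasis or
macrometastasis), the MSKCC nomogram's predicted probability of non-sentinel
node (NSN) involvement, the observed number of metastatic non-sentinel nodes
on completion axillary dissection, and optional clinico-pathologic covariates.

This module owns the domain types, their invariants, CSV round-tripping and
the descriptive cohort summary; classification, validation and costing build
on it.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "SNType",
    "TumorType",
    "PTStage",
    "RiskGroup",
    "NSNStatus",
    "PatientRecord",
    "Cohort",
    "StratifiedCounts",
    "CohortSchemaError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "stratify",
    "summarize",
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
]


class CohortSchemaError(ValueError):
    """The CSV header does not match the documented cohort schema."""


class CohortValidationError(ValueError):
    """A row or record violates a domain invariant."""


class SNType(str, enum.Enum):
    """Size category of the sentinel-node metastasis (pTNM nodal sub-stage)."""

    ITC = "itc"        # isolated tumor cells, pN0(i+), deposit <= 0.2 mm
    MICRO = "micro"    # micrometastasis, pN1(mic), > 0.2 mm and <= 2 mm
    MACRO = "macro"    # macrometastasis, pN1, > 2 mm

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class TumorType(str, enum.Enum):
    DUCTAL = "ductal"
    LOBULAR = "lobular"


class PTStage(str, enum.Enum):
    PT1 = "pT1"
    PT2 = "pT2"
    PT3 = "pT3"


class RiskGroup(str, enum.Enum):
    """Nomogram risk group relative to a score threshold t: LOW iff score <= t."""

    LOW = "low"
    HIGH = "high"


class NSNStatus(str, enum.Enum):
    """Observed non-sentinel node status on completion axillary dissection."""

    NEG = "neg"
    POS = "pos"


# Pathology synonyms accepted on read (case-insensitive).
_SN_ALIASES: dict[str, SNType] = {
    "itc": SNType.ITC,
    "pn0(i+)": SNType.ITC,
    "pn0i+": SNType.ITC,
    "micro": SNType.MICRO,
    "micrometastasis": SNType.MICRO,
    "pn1(mic)": SNType.MICRO,
    "pn1mic": SNType.MICRO,
    "macro": SNType.MACRO,
    "macrometastasis": SNType.MACRO,
    "pn1": SNType.MACRO,
}

REQUIRED_COLUMNS: tuple[str, ...] = ("patient_id", "sn_type", "mskcc_score", "n_pos_nsn")
OPTIONAL_COLUMNS: tuple[str, ...] = (
    "n_pos_sn",
    "age_years",
    "tumor_type",
    "tumor_size_mm",
    "pt_stage",
    "grade",
    "lvi",
)


@dataclass(frozen=True)
class PatientRecord:
    """One sentinel-node-positive patient.

    ``mskcc_score`` is the nomogram's predicted probability of non-sentinel
    node involvement, taken as given (the nomogram itself is an external
    calculator); ``n_pos_nsn`` is the count of metastatic non-sentinel nodes
    found on completion axillary dissection, the ground truth against which
    the score is judged.
    """

    patient_id: str
    sn_type: SNType
    mskcc_score: float
    n_pos_nsn: int
    n_pos_sn: int = 1
    age_years: Optional[float] = None
    tumor_type: Optional[TumorType] = None
    tumor_size_mm: Optional[float] = None
    pt_stage: Optional[PTStage] = None
    grade: Optional[int] = None
    lvi: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise CohortValidationError("patient_id must be non-empty")
        if not isinstance(self.sn_type, SNType):
            raise CohortValidationError(f"unknown sn_type {self.sn_type!r}")
        if not (0.0 <= self.mskcc_score <= 1.0) or math.isnan(self.mskcc_score):
            raise CohortValidationError(
                f"mskcc_score must lie in [0, 1], got {self.mskcc_score!r}"
            )
        if self.n_pos_nsn < 0 or int(self.n_pos_nsn) != self.n_pos_nsn:
            raise CohortValidationError(f"n_pos_nsn must be a non-negative integer, got {self.n_pos_nsn!r}")
        if self.n_pos_sn < 1 or int(self.n_pos_sn) != self.n_pos_sn:
            raise CohortValidationError(f"n_pos_sn must be a positive integer, got {self.n_pos_sn!r}")
        if self.age_years is not None and self.age_years <= 0:
            raise CohortValidationError(f"age_years must be positive, got {self.age_years!r}")
        if self.tumor_size_mm is not None and self.tumor_size_mm < 0:
            raise CohortValidationError(f"tumor_size_mm must be non-negative, got {self.tumor_size_mm!r}")
        if self.grade is not None and self.grade not in (1, 2, 3):
            raise CohortValidationError(f"grade must be 1, 2 or 3, got {self.grade!r}")

    @property
    def nsn_positive(self) -> bool:
        """True iff completion dissection found at least one metastatic NSN."""
        return self.n_pos_nsn > 0


@dataclass(frozen=True)
class Cohort:
    """Ordered, non-empty collection of patients with unique identifiers."""

    patients: tuple[PatientRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "patients", tuple(self.patients))
        if len(self.patients) == 0:
            raise CohortValidationError("a cohort must contain at least one patient")
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise CohortValidationError(f"duplicate patient_id {dup!r}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.patients)

    def scores(self) -> list[float]:
        return [p.mskcc_score for p in self.patients]

    def labels(self) -> list[bool]:
        """NSN positivity per patient, in cohort order."""
        return [p.nsn_positive for p in self.patients]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "sn_type": p.sn_type.value,
                    "mskcc_score": p.mskcc_score,
                    "n_pos_nsn": p.n_pos_nsn,
                    "n_pos_sn": p.n_pos_sn,
                    "age_years": p.age_years,
                    "tumor_type": p.tumor_type.value if p.tumor_type else None,
                    "tumor_size_mm": p.tumor_size_mm,
                    "pt_stage": p.pt_stage.value if p.pt_stage else None,
                    "grade": p.grade,
                    "lvi": None if p.lvi is None else int(p.lvi),
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class StratifiedCounts:
    """Patient counts cross-classified by risk group x SN type x NSN status.

    The partition rule is LOW iff score <= threshold; cells always sum to the
    cohort size.
    """

    threshold: float
    counts: Mapping[tuple[RiskGroup, SNType, NSNStatus], int]

    def __post_init__(self) -> None:
        full = {
            (r, t, s): int(self.counts.get((r, t, s), 0))
            for r in RiskGroup
            for t in SNType
            for s in NSNStatus
        }
        if any(v < 0 for v in full.values()):
            raise CohortValidationError("stratified cell counts must be non-negative")
        object.__setattr__(self, "counts", full)

    def cell(self, risk: RiskGroup, sn_type: SNType, nsn: NSNStatus) -> int:
        return self.counts[(risk, sn_type, nsn)]

    def group_type(self, risk: RiskGroup, sn_type: SNType) -> int:
        return sum(self.counts[(risk, sn_type, s)] for s in NSNStatus)

    def group_total(self, risk: RiskGroup) -> int:
        return sum(self.group_type(risk, t) for t in SNType)

    def type_total(self, sn_type: SNType) -> int:
        return sum(self.group_type(r, sn_type) for r in RiskGroup)

    def group_nsn(self, risk: RiskGroup, nsn: NSNStatus) -> int:
        return sum(self.counts[(risk, t, nsn)] for t in SNType)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "risk_group": r.value,
                "sn_type": t.value,
                "nsn_status": s.value,
                "count": self.counts[(r, t, s)],
            }
            for r in RiskGroup
            for t in SNType
            for s in NSNStatus
        ]
        return pd.DataFrame(rows)


def _parse_sn_type(raw: str) -> SNType:
    key = raw.strip().lower()
    if key not in _SN_ALIASES:
        raise CohortValidationError(f"unknown sn_type label {raw!r}")
    return _SN_ALIASES[key]


def _parse_optional(row: Mapping[str, object], col: str):
    if col not in row:
        return None
    v = row[col]
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return v


def _record_from_row(row: Mapping[str, object], rownum: int) -> PatientRecord:
    try:
        kwargs: dict[str, object] = {
            "patient_id": str(row["patient_id"]),
            "sn_type": _parse_sn_type(str(row["sn_type"])),
            "mskcc_score": float(row["mskcc_score"]),  # type: ignore[arg-type]
            "n_pos_nsn": int(float(row["n_pos_nsn"])),  # type: ignore[arg-type]
        }
        v = _parse_optional(row, "n_pos_sn")
        if v is not None:
            kwargs["n_pos_sn"] = int(float(v))  # type: ignore[arg-type]
        v = _parse_optional(row, "age_years")
        if v is not None:
            kwargs["age_years"] = float(v)  # type: ignore[arg-type]
        v = _parse_optional(row, "tumor_type")
        if v is not None:
            kwargs["tumor_type"] = TumorType(str(v).strip().lower())
        v = _parse_optional(row, "tumor_size_mm")
        if v is not None:
            kwargs["tumor_size_mm"] = float(v)  # type: ignore[arg-type]
        v = _parse_optional(row, "pt_stage")
        if v is not None:
            kwargs["pt_stage"] = PTStage(str(v).strip().lower().replace("pt", "pT"))
        v = _parse_optional(row, "grade")
        if v is not None:
            kwargs["grade"] = int(float(v))  # type: ignore[arg-type]
        v = _parse_optional(row, "lvi")
        if v is not None:
            kwargs["lvi"] = bool(int(float(v)))  # type: ignore[arg-type]
        return PatientRecord(**kwargs)  # type: ignore[arg-type]
    except CohortValidationError as exc:
        raise CohortValidationError(f"row {rownum}: {exc}") from None
    except (ValueError, TypeError) as exc:
        raise CohortValidationError(f"row {rownum}: {exc}") from None


def read_cohort(path: str | Path, strict: bool = True) -> Cohort:
    """Read a cohort CSV.

    Required columns: ``patient_id, sn_type, mskcc_score, n_pos_nsn``;
    optional: ``n_pos_sn, age_years, tumor_type, tumor_size_mm, pt_stage,
    grade, lvi``.  Missing optional values are written/read as ``NA`` and
    booleans as 0/1.  With ``strict=True`` unknown columns raise a schema
    error; otherwise they are ignored.
    """
    path = Path(path)
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing required column(s): {', '.join(missing)}")
    known = set(REQUIRED_COLUMNS) | set(OPTIONAL_COLUMNS)
    extra = [c for c in df.columns if c not in known]
    if extra and strict:
        raise CohortSchemaError(f"unknown column(s): {', '.join(extra)}")
    records = [
        _record_from_row(row, i + 2)  # +2: 1-based plus header line
        for i, row in enumerate(df.to_dict(orient="records"))
    ]
    return Cohort(tuple(records), provenance=str(path))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to CSV so that ``read_cohort`` round-trips it losslessly."""
    df = cohort.to_dataframe()
    df.to_csv(path, index=False, na_rep="NA")


def stratify(cohort: Cohort, threshold: float) -> StratifiedCounts:
    """Cross-classify a cohort at a score threshold.

    LOW risk iff ``mskcc_score <= threshold`` (ties go LOW); within each risk
    group patients are broken down by SN metastasis type and observed
    non-sentinel node status.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie strictly in (0, 1), got {threshold}")
    counts: dict[tuple[RiskGroup, SNType, NSNStatus], int] = {}
    for p in cohort:
        risk = RiskGroup.LOW if p.mskcc_score <= threshold else RiskGroup.HIGH
        nsn = NSNStatus.POS if p.nsn_positive else NSNStatus.NEG
        key = (risk, p.sn_type, nsn)
        counts[key] = counts.get(key, 0) + 1
    return StratifiedCounts(threshold=threshold, counts=counts)


_AGE_BINS = ((0, 50, "30-50"), (50, 60, "50-60"), (60, 200, "60-90"))
_NODE_BINS = ((1, "1"), (2, "2"), (3, "3"))  # then ">3"


def _bin_count(values: Sequence[int], bins=_NODE_BINS) -> list[tuple[str, int]]:
    out = [(label, sum(1 for v in values if v == k)) for k, label in bins]
    out.append((">3", sum(1 for v in values if v > bins[-1][0])))
    return out


def summarize(cohort: Cohort) -> pd.DataFrame:
    """Descriptive cohort summary: counts and percentages per category, median
    (range) for age and tumor size.  Missing optional covariates appear as an
    ``NA`` level so every characteristic accounts for the whole cohort.
    """
    n = len(cohort)
    rows: list[dict[str, object]] = []

    def add(char: str, level: str, count: int) -> None:
        rows.append(
            {
                "characteristic": char,
                "level": level,
                "n": count,
                "percent": 100.0 * count / n,
                "median": None,
                "min": None,
                "max": None,
            }
        )

    def add_median(char: str, values: list[float]) -> None:
        s = pd.Series(values, dtype=float)
        rows.append(
            {
                "characteristic": char,
                "level": "median (range)",
                "n": len(values),
                "percent": None,
                "median": float(s.median()) if len(values) else None,
                "min": float(s.min()) if len(values) else None,
                "max": float(s.max()) if len(values) else None,
            }
        )

    ages = [p.age_years for p in cohort if p.age_years is not None]
    add_median("age_years", ages)
    for lo, hi, label in _AGE_BINS:
        add("age_years", label, sum(1 for a in ages if lo <= a < hi))
    add("age_years", "NA", n - len(ages))

    for tt in TumorType:
        add("tumor_type", tt.value, sum(1 for p in cohort if p.tumor_type is tt))
    add("tumor_type", "NA", sum(1 for p in cohort if p.tumor_type is None))

    sizes = [p.tumor_size_mm for p in cohort if p.tumor_size_mm is not None]
    add_median("tumor_size_mm", sizes)
    for st in PTStage:
        add("pt_stage", st.value, sum(1 for p in cohort if p.pt_stage is st))
    add("pt_stage", "NA", sum(1 for p in cohort if p.pt_stage is None))

    add("lvi", "positive", sum(1 for p in cohort if p.lvi is True))
    add("lvi", "negative", sum(1 for p in cohort if p.lvi is False))
    add("lvi", "NA", sum(1 for p in cohort if p.lvi is None))

    for g in (1, 2, 3):
        add("grade", str(g), sum(1 for p in cohort if p.grade == g))
    add("grade", "NA", sum(1 for p in cohort if p.grade is None))

    for t in SNType:
        add("sn_type", t.value, sum(1 for p in cohort if p.sn_type is t))

    for label, count in _bin_count([p.n_pos_sn for p in cohort]):
        add("n_pos_sn", label, count)

    nsn = [p.n_pos_nsn for p in cohort]
    add("n_pos_nsn", "0", sum(1 for v in nsn if v == 0))
    for label, count in _bin_count(nsn):
        add("n_pos_nsn", label, count)

    add_median("mskcc_score", [p.mskcc_score for p in cohort])
    return pd.DataFrame(rows)
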