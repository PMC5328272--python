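"""Cohort domain types, CSV round-trip and stratification."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from axicost import (
    Cohort,
    CohortSchemaError,
    CohortValidationError,
    NSNStatus,
    PatientRecord,
    PTStage,
    RiskGroup,
    SNType,
    TumorType,
    read_cohort,
    stratify,
    summarize,
    write_cohort,
)
from axicost.cohort import OPTIONAL_COLUMNS

from conftest import random_cohort


def make_patient(pid="p1", score=0.5, sn=SNType.MICRO, nsn=0, **kw) -> PatientRecord:
    return PatientRecord(patient_id=pid, sn_type=sn, mskcc_score=score, n_pos_nsn=nsn, **kw)


class TestPatientRecord:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"score": 1.2},
            {"score": -0.1},
            {"score": float("nan")},
            {"nsn": -1},
            {"kw": {"age_years": -5.0}},
            {"kw": {"grade": 4}},
            {"kw": {"n_pos_sn": 0}},
        ],
    )
    def test_invariant_violations_rejected(self, kwargs):
        kw = kwargs.pop("kw", {})
        with pytest.raises(CohortValidationError):
            make_patient(**kwargs, **kw)

    def test_nsn_positive_iff_count_positive(self):
        assert not make_patient(nsn=0).nsn_positive
        assert make_patient(nsn=3).nsn_positive

    def test_duplicate_ids_rejected(self):
        with pytest.raises(CohortValidationError, match="duplicate"):
            Cohort((make_patient("a"), make_patient("a")))

    def test_empty_cohort_rejected(self):
        with pytest.raises(CohortValidationError):
            Cohort(())


class TestCSVRoundTrip:
    def test_read_preserves_order_and_values(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(
            "patient_id,sn_type,mskcc_score,n_pos_nsn\n"
            "a,ITC,0.1,0\nb,micro,0.3,2\nc,pN1,0.9,1\n"
        )
        cohort = read_cohort(path)
        assert len(cohort) == 3
        assert [p.patient_id for p in cohort] == ["a", "b", "c"]
        assert [p.mskcc_score for p in cohort] == [0.1, 0.3, 0.9]
        # pathology synonyms parsed case-insensitively
        assert [p.sn_type for p in cohort] == [SNType.ITC, SNType.MICRO, SNType.MACRO]

    def test_score_out_of_bounds_names_row(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(
            "patient_id,sn_type,mskcc_score,n_pos_nsn\na,itc,0.5,0\nb,itc,1.2,0\n"
        )
        with pytest.raises(CohortValidationError, match="row 3"):
            read_cohort(path)

    def test_missing_required_column_named(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("patient_id,sn_type,n_pos_nsn\na,itc,0\n")
        with pytest.raises(CohortSchemaError, match="mskcc_score"):
            read_cohort(path)

    def test_unknown_sn_type_rejected(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("patient_id,sn_type,mskcc_score,n_pos_nsn\na,huge,0.5,0\n")
        with pytest.raises(CohortValidationError, match="sn_type"):
            read_cohort(path)

    def test_strict_rejects_unknown_columns(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("patient_id,sn_type,mskcc_score,n_pos_nsn,color\na,itc,0.5,0,red\n")
        with pytest.raises(CohortSchemaError, match="color"):
            read_cohort(path, strict=True)
        assert len(read_cohort(path, strict=False)) == 1

    def test_round_trip_lossless_all_fields(self, tmp_path):
        full = make_patient(
            "full",
            score=0.42,
            sn=SNType.MACRO,
            nsn=2,
            n_pos_sn=3,
            age_years=61.5,
            tumor_type=TumorType.LOBULAR,
            tumor_size_mm=17.0,
            pt_stage=PTStage.PT2,
            grade=3,
            lvi=True,
        )
        sparse = make_patient("sparse", score=0.0, nsn=0)
        cohort = Cohort((full, sparse))
        path = tmp_path / "rt.csv"
        write_cohort(cohort, path)
        back = read_cohort(path)
        assert back.patients == cohort.patients

    def test_round_trip_random_cohorts(self, tmp_path):
        for seed in (0, 1, 2):
            cohort = random_cohort(seed)
            path = tmp_path / f"r{seed}.csv"
            write_cohort(cohort, path)
            assert read_cohort(path).patients == cohort.patients


class TestStratify:
    def test_reference_cohort_reproduces_published_cells(self, ref_cohort):
        sc = stratify(ref_cohort, 0.3)
        assert sc.total == 1036
        low = [sc.group_type(RiskGroup.LOW, t) for t in SNType]
        high = [sc.group_type(RiskGroup.HIGH, t) for t in SNType]
        assert low == [171, 274, 91]
        assert high == [2, 25, 473]
        assert sc.group_nsn(RiskGroup.LOW, NSNStatus.NEG) == 470
        assert sc.group_nsn(RiskGroup.HIGH, NSNStatus.NEG) == 299
        assert sc.group_total(RiskGroup.LOW) == 536
        assert sc.group_total(RiskGroup.HIGH) == 500

    def test_threshold_above_all_scores_puts_everyone_low(self, ref_cohort):
        sc = stratify(ref_cohort, 0.99)
        assert sc.group_total(RiskGroup.LOW) == len(ref_cohort)
        assert sc.group_total(RiskGroup.HIGH) == 0

    @pytest.mark.parametrize("seed,threshold", [(0, 0.3), (1, 0.5), (2, 0.15)])
    def test_cells_match_per_patient_enumeration(self, seed, threshold):
        cohort = random_cohort(seed)
        sc = stratify(cohort, threshold)
        for r in RiskGroup:
            for t in SNType:
                for s in NSNStatus:
                    expected = sum(
                        1
                        for p in cohort
                        if (RiskGroup.LOW if p.mskcc_score <= threshold else RiskGroup.HIGH) is r
                        and p.sn_type is t
                        and (NSNStatus.POS if p.n_pos_nsn > 0 else NSNStatus.NEG) is s
                    )
                    assert sc.cell(r, t, s) == expected
        assert sc.total == len(cohort)

    @settings(derandomize=True, max_examples=50)
    @given(
        seed=st.integers(0, 50),
        t1=st.floats(0.05, 0.95),
        t2=st.floats(0.05, 0.95),
    )
    def test_partition_complete_and_monotone(self, seed, t1, t2):
        cohort = random_cohort(seed, n=25)
        lo, hi = sorted((t1, t2))
        sc_lo, sc_hi = stratify(cohort, lo), stratify(cohort, hi)
        assert sc_lo.total == sc_hi.total == len(cohort)
        # raising the threshold never shrinks the LOW group
        assert sc_hi.group_total(RiskGroup.LOW) >= sc_lo.group_total(RiskGroup.LOW)

    def test_invalid_threshold_rejected(self, ref_cohort):
        with pytest.raises(ValueError):
            stratify(ref_cohort, 0.0)
        with pytest.raises(ValueError):
            stratify(ref_cohort, 1.0)


class TestSummarize:
    def test_sn_type_proportions_on_reference(self, ref_cohort):
        df = summarize(ref_cohort)
        sn = df[df.characteristic == "sn_type"].set_index("level")
        assert sn.loc["itc", "n"] == 173
        assert sn.loc["micro", "n"] == 299
        assert sn.loc["macro", "n"] == 564
        assert math.isclose(sn.loc["itc", "percent"], 100 * 173 / 1036)
        assert math.isclose(sn.loc["macro", "percent"], 100 * 564 / 1036)

    def test_single_patient_is_100_percent(self):
        cohort = Cohort((make_patient(age_years=50.0),))
        df = summarize(cohort)
        row = df[(df.characteristic == "sn_type") & (df.level == "micro")]
        assert row.percent.iloc[0] == 100.0

    def test_each_categorical_characteristic_accounts_for_everyone(self, small_cohort):
        df = summarize(small_cohort)
        counts = df[df.percent.notna()].groupby("characteristic")["n"].sum()
        # n_pos_nsn has both the explicit 0 level and the positive-count bins
        for char in ("sn_type", "tumor_type", "lvi", "grade", "pt_stage", "n_pos_sn"):
            assert counts[char] == len(small_cohort)
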