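"""Tests for EMR ingestion, normalization, labelling and the exposure matrix."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from prescriptome.ingest import (
    DrugNormalizationMap,
    ReferentialIntegrityError,
    SchemaError,
    build_exposure_matrix,
    cohort_summary,
    label_readmission,
    normalize_drugs,
    read_emr_tables,
    UNMAPPED,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


PATIENT_HEADER = "patient_id\tage\tsex\trace\tadmit_date\tdischarge_date\treadmit_date\n"


def _patients_df(rows):
    """Labeled patients table from (id, age, sex, discharge, readmit) tuples."""
    recs = []
    for pid, age, sex, discharge, readmit in rows:
        recs.append(
            {
                "patient_id": pid,
                "age": age,
                "sex": sex,
                "race": "x",
                "admit_date": dt.date(2014, 1, 1),
                "discharge_date": discharge,
                "readmit_date": readmit,
            }
        )
    return pd.DataFrame(recs)


class TestReadEmrTables:
    def test_valid_rows_parsed(self, tmp_path):
        _write(
            tmp_path,
            "patients.tsv",
            PATIENT_HEADER
            + "p1\t44\tmale\tw\t2014-01-01\t2014-01-10\t\n"
            + "p2\t30\tfemale\tw\t2014-02-01\t2014-02-05\t2014-02-20\n"
            + "p3\t52\tother\tw\t2014-03-01\t2014-03-02\t\n",
        )
        _write(tmp_path, "prescriptions.tsv", "patient_id\tdrug_raw\tdrug_id\np1\tASPIRIN\t\n")
        _write(tmp_path, "diagnoses.tsv", "patient_id\tdx_code\tdx_name\np1\tDX001\tMDD\n")
        patients, rx, dx, rejects = read_emr_tables(tmp_path)
        assert len(patients) == 3 and not rejects
        assert patients.loc[0, "admit_date"] == dt.date(2014, 1, 1)

    def test_malformed_age_isolated(self, tmp_path):
        _write(
            tmp_path,
            "patients.tsv",
            PATIENT_HEADER
            + "p1\tabc\tmale\tw\t2014-01-01\t2014-01-10\t\n"
            + "p2\t30\tfemale\tw\t2014-02-01\t2014-02-05\t\n",
        )
        _write(tmp_path, "prescriptions.tsv", "patient_id\tdrug_raw\tdrug_id\n")
        _write(tmp_path, "diagnoses.tsv", "patient_id\tdx_code\tdx_name\n")
        patients, _, _, rejects = read_emr_tables(tmp_path)
        assert len(patients) == 1
        assert len(rejects) == 1 and "age" in rejects[0].reason

    def test_header_only_files(self, tmp_path):
        _write(tmp_path, "patients.tsv", PATIENT_HEADER)
        _write(tmp_path, "prescriptions.tsv", "patient_id\tdrug_raw\tdrug_id\n")
        _write(tmp_path, "diagnoses.tsv", "patient_id\tdx_code\tdx_name\n")
        patients, rx, dx, rejects = read_emr_tables(tmp_path)
        assert len(patients) == 0 and len(rx) == 0 and not rejects

    def test_missing_column_fatal(self, tmp_path):
        _write(tmp_path, "patients.tsv", "patient_id\tage\n")
        _write(tmp_path, "prescriptions.tsv", "patient_id\tdrug_raw\tdrug_id\n")
        _write(tmp_path, "diagnoses.tsv", "patient_id\tdx_code\tdx_name\n")
        with pytest.raises(SchemaError, match="sex"):
            read_emr_tables(tmp_path)


class TestNormalizeDrugs:
    MAP = DrugNormalizationMap({"pravastatin": "pravastatin", "plavix": "clopidogrel"})

    def test_case_folding(self):
        rx = pd.DataFrame({"patient_id": ["p1"], "drug_raw": ["PRAVASTATIN"], "drug_id": [""]})
        out, n = normalize_drugs(rx, self.MAP)
        assert out.loc[0, "drug_id"] == "pravastatin" and n == 0

    def test_unmatched_flagged(self):
        rx = pd.DataFrame({"patient_id": ["p1"], "drug_raw": ["mystery"], "drug_id": [""]})
        out, n = normalize_drugs(rx, self.MAP)
        assert out.loc[0, "drug_id"] == UNMAPPED and n == 1

    def test_synonyms_share_id(self):
        rx = pd.DataFrame(
            {"patient_id": ["p1", "p2"], "drug_raw": ["Plavix", "plavix"], "drug_id": ["", ""]}
        )
        out, _ = normalize_drugs(rx, self.MAP)
        assert set(out["drug_id"]) == {"clopidogrel"}


class TestLabelReadmission:
    def test_window_boundaries(self):
        d = dt.date(2014, 5, 1)
        pa = _patients_df(
            [
                ("in30", 30, "male", d, d + dt.timedelta(days=30)),
                ("out31", 30, "male", d, d + dt.timedelta(days=31)),
                ("none", 30, "male", d, None),
            ]
        )
        labeled, rejects = label_readmission(pa)
        got = dict(zip(labeled["patient_id"], labeled["readmitted_30d"]))
        assert got == {"in30": True, "out31": False, "none": False} and not rejects

    def test_same_day_readmit_rejected(self):
        d = dt.date(2014, 5, 1)
        pa = _patients_df([("bad", 30, "male", d, d)])
        labeled, rejects = label_readmission(pa)
        assert len(labeled) == 0 and len(rejects) == 1

    def test_partition_exhaustive_exclusive(self, default_cohort):
        labeled, _ = label_readmission(default_cohort.patients.drop(columns="readmitted_30d"))
        assert labeled["readmitted_30d"].isin([True, False]).all()
        assert labeled["readmitted_30d"].sum() + (~labeled["readmitted_30d"]).sum() == len(labeled)


class TestExposureMatrix:
    def _toy(self):
        d = dt.date(2014, 5, 1)
        pa = _patients_df(
            [("p1", 40, "male", d, None), ("p2", 50, "female", d, None), ("p3", 60, "male", d, None)]
        )
        pa, _ = label_readmission(pa)
        rx = pd.DataFrame(
            {
                "patient_id": ["p1", "p1", "p1", "p2", "p3"],
                "drug_raw": ["a", "a", "a", "b", "a"],
                "drug_id": ["aspirin", "aspirin", "aspirin", "bisacodyl", "aspirin"],
            }
        )
        return pa, rx

    def test_duplicates_collapse(self):
        pa, rx = self._toy()
        m = build_exposure_matrix(pa, rx)
        assert m.cells[0].sum() == 1  # 3 aspirin records -> one exposure

    def test_toy_matrix_layout(self):
        pa, rx = self._toy()
        m = build_exposure_matrix(pa, rx)
        assert m.drugs == ["aspirin", "bisacodyl"]  # lexicographic
        assert m.cells.tolist() == [[1, 0], [0, 1], [1, 0]]

    def test_row_sums_match_distinct_drug_counts(self, default_cohort, exposure_matrix):
        rx = default_cohort.prescriptions
        distinct = rx.groupby("patient_id")["drug_id"].nunique()
        expected = default_cohort.patients["patient_id"].map(distinct).fillna(0).to_numpy()
        assert np.array_equal(exposure_matrix.cells.sum(axis=1), expected)

    def test_row_order_invariance(self, small_cohort):
        rx = small_cohort.prescriptions
        m1 = build_exposure_matrix(small_cohort.patients, rx)
        m2 = build_exposure_matrix(
            small_cohort.patients, rx.sample(frac=1, random_state=3).reset_index(drop=True)
        )
        assert np.array_equal(m1.cells, m2.cells) and m1.drugs == m2.drugs

    def test_unknown_patient_fatal(self):
        pa, rx = self._toy()
        rx.loc[0, "patient_id"] = "ghost"
        with pytest.raises(ReferentialIntegrityError):
            build_exposure_matrix(pa, rx)

    def test_unmapped_excluded(self):
        pa, rx = self._toy()
        rx["drug_id"] = UNMAPPED
        m = build_exposure_matrix(pa, rx)
        assert m.cells.shape == (3, 0)


class TestCohortSummary:
    def test_hand_computed_toy(self):
        d = dt.date(2014, 5, 1)
        pa = _patients_df(
            [
                ("c1", 40, "male", d, d + dt.timedelta(days=5)),
                ("c2", 50, "female", d, d + dt.timedelta(days=10)),
                ("n1", 20, "male", d, None),
                ("n2", 30, "male", d, None),
            ]
        )
        pa, _ = label_readmission(pa)
        rx = pd.DataFrame(
            {
                "patient_id": ["c1", "c1", "c2", "n1"],
                "drug_raw": ["x"] * 4,
                "drug_id": ["aspirin", "senna", "aspirin", "senna"],
            }
        )
        s = cohort_summary(pa, rx)
        case = s.loc["readmitted"]
        ctrl = s.loc["no_readmission"]
        assert case["n"] == 2 and ctrl["n"] == 2
        assert case["mean_age"] == 45.0 and ctrl["mean_age"] == 25.0
        assert case["pct_male"] == 50.0 and ctrl["pct_male"] == 100.0
        assert case["mean_prescriptions"] == 1.5 and ctrl["mean_prescriptions"] == 0.5
        assert case["distinct_drugs"] == 2 and ctrl["distinct_drugs"] == 1

    def test_case_percentage_two_dp(self, default_cohort):
        s = cohort_summary(default_cohort.patients, default_cohort.prescriptions)
        assert round(s.loc["readmitted", "pct"], 2) == 6.98
        assert round(s.loc["no_readmission", "pct"], 2) == 93.02  # 1186/1275

    def test_identical_groups_welch_p_one(self):
        d = dt.date(2014, 5, 1)
        pa = _patients_df(
            [
                ("c1", 40, "male", d, d + dt.timedelta(days=5)),
                ("c2", 40, "male", d, d + dt.timedelta(days=5)),
                ("n1", 40, "male", d, None),
                ("n2", 40, "male", d, None),
            ]
        )
        pa, _ = label_readmission(pa)
        rx = pd.DataFrame(
            {
                "patient_id": ["c1", "c2", "n1", "n2"],
                "drug_raw": ["x"] * 4,
                "drug_id": ["aspirin"] * 4,
            }
        )
        s = cohort_summary(pa, rx)
        assert s.attrs["welch_prescriptions"]["p"] == 1.0

    def test_empty_group_warns(self):
        d = dt.date(2014, 5, 1)
        pa = _patients_df([("n1", 30, "male", d, None)])
        pa, _ = label_readmission(pa)
        rx = pd.DataFrame({"patient_id": [], "drug_raw": [], "drug_id": []})
        with pytest.warns(UserWarning, match="no patients"):
            s = cohort_summary(pa, rx)
        assert s.loc["readmitted", "n"] == 0
        assert np.isnan(s.loc["readmitted", "mean_age"])
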