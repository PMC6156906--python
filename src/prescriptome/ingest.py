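"""EMR table ingestion: read TSV extracts, normalize drug names, label the
30-day readmission outcome and build the binary patient x drug exposure
matrix.

The 30-day window is inclusive of day 30 and exclusive of day 0 (a same-day
transfer is not a readmission), matching the CMS convention.  Drug
normalization is a deterministic, case-insensitive lookup against a static
map — no fuzzy matching — and unmatched raw names are flagged ``UNMAPPED``
rather than dropped.  No patient exclusion filters are applied.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import welch_t_test

__all__ = [
    "UNMAPPED",
    "Reject",
    "DrugNormalizationMap",
    "ExposureMatrix",
    "SchemaError",
    "ReferentialIntegrityError",
    "read_emr_tables",
    "read_drug_map",
    "normalize_drugs",
    "label_readmission",
    "build_exposure_matrix",
    "cohort_summary",
]

UNMAPPED = "UNMAPPED"

PATIENT_COLUMNS = [
    "patient_id", "age", "sex", "race", "admit_date", "discharge_date", "readmit_date",
]
PRESCRIPTION_COLUMNS = ["patient_id", "drug_raw", "drug_id"]
DIAGNOSIS_COLUMNS = ["patient_id", "dx_code", "dx_name"]

SEX_VOCABULARY = {"male", "female", "other", "unknown"}


class SchemaError(ValueError):
    """A required column is missing from an input file."""


class ReferentialIntegrityError(ValueError):
    """A child table references a patient absent from the patients table."""


@dataclass(frozen=True)
class Reject:
    file: str
    row: int
    reason: str


@dataclass(frozen=True)
class DrugNormalizationMap:
    """Case-insensitive raw-name -> canonical drug id lookup."""

    entries: dict[str, str]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DrugNormalizationMap":
        _require(df, ["drug_raw", "drug_id"], "drugmap")
        return cls({str(r).strip().lower(): str(i).strip() for r, i in zip(df["drug_raw"], df["drug_id"])})

    def lookup(self, raw: str) -> str:
        return self.entries.get(str(raw).strip().lower(), UNMAPPED)


@dataclass
class ExposureMatrix:
    """Binary patient x drug incidence with outcome and covariates."""

    patients: list[str]
    drugs: list[str]
    cells: np.ndarray                      # (n_patients, n_drugs) in {0, 1}
    outcome: np.ndarray                    # bool, case = True
    covariates: pd.DataFrame               # index-aligned: age, sex
    strata: pd.Series | None = None        # optional per-patient stratum label

    def exposure(self, drug: str) -> np.ndarray:
        return self.cells[:, self.drugs.index(drug)]

    @property
    def n_cases(self) -> int:
        return int(self.outcome.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.outcome).sum())


def _require(df: pd.DataFrame, columns: list[str], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required column(s) {missing}")


def _parse_date(value) -> dt.date | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if not s:
        return None
    return dt.date.fromisoformat(s)


def read_emr_tables(
    directory=None,
    *,
    patients_path=None,
    prescriptions_path=None,
    diagnoses_path=None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[Reject]]:
    """Read patients / prescriptions / diagnoses TSVs.

    Malformed rows are collected into the returned rejects report rather
    than silently dropped; a missing required column is fatal.
    """
    if directory is not None:
        d = Path(directory)
        patients_path = patients_path or d / "patients.tsv"
        prescriptions_path = prescriptions_path or d / "prescriptions.tsv"
        diagnoses_path = diagnoses_path or d / "diagnoses.tsv"
    rejects: list[Reject] = []

    raw = pd.read_csv(patients_path, sep="\t", dtype=str, keep_default_na=False)
    _require(raw, PATIENT_COLUMNS, str(patients_path))
    rows = []
    for i, rec in raw.iterrows():
        try:
            age = int(str(rec["age"]).strip())
        except ValueError:
            rejects.append(Reject(str(patients_path), int(i), f"unparseable age {rec['age']!r}"))
            continue
        sex = str(rec["sex"]).strip().lower() or "unknown"
        if sex not in SEX_VOCABULARY:
            sex = "unknown"
        try:
            admit = _parse_date(rec["admit_date"])
            discharge = _parse_date(rec["discharge_date"])
            readmit = _parse_date(rec["readmit_date"])
        except ValueError as e:
            rejects.append(Reject(str(patients_path), int(i), f"unparseable date: {e}"))
            continue
        if admit is None or discharge is None:
            rejects.append(Reject(str(patients_path), int(i), "missing admit/discharge date"))
            continue
        if discharge < admit:
            rejects.append(Reject(str(patients_path), int(i), "discharge before admission"))
            continue
        rows.append(
            {
                "patient_id": str(rec["patient_id"]).strip(),
                "age": age,
                "sex": sex,
                "race": str(rec["race"]).strip(),
                "admit_date": admit,
                "discharge_date": discharge,
                "readmit_date": readmit,
            }
        )
    patients = pd.DataFrame(rows, columns=PATIENT_COLUMNS)

    prescriptions = pd.read_csv(prescriptions_path, sep="\t", dtype=str, keep_default_na=False)
    _require(prescriptions, PRESCRIPTION_COLUMNS, str(prescriptions_path))
    prescriptions = prescriptions[PRESCRIPTION_COLUMNS].copy()

    diagnoses = pd.read_csv(diagnoses_path, sep="\t", dtype=str, keep_default_na=False)
    _require(diagnoses, DIAGNOSIS_COLUMNS, str(diagnoses_path))
    diagnoses = diagnoses[DIAGNOSIS_COLUMNS].copy()

    return patients, prescriptions, diagnoses, rejects


def read_drug_map(path) -> DrugNormalizationMap:
    return DrugNormalizationMap.from_frame(pd.read_csv(path, sep="\t", dtype=str))


def normalize_drugs(
    prescriptions: pd.DataFrame, drug_map: DrugNormalizationMap
) -> tuple[pd.DataFrame, int]:
    """Fill ``drug_id`` by case-insensitive exact lookup; returns the
    normalized table and the count of UNMAPPED records."""
    out = prescriptions.copy()
    out["drug_id"] = [drug_map.lookup(r) for r in out["drug_raw"]]
    return out, int((out["drug_id"] == UNMAPPED).sum())


def label_readmission(
    patients: pd.DataFrame, window_days: int = 30
) -> tuple[pd.DataFrame, list[Reject]]:
    """Label ``readmitted_30d``: readmission day in [1, window_days] after
    discharge.  Rows whose readmit date is on or before discharge are
    rejected (they violate the record invariant), not silently relabeled."""
    rejects: list[Reject] = []
    keep = []
    labels = []
    for i, rec in patients.iterrows():
        readmit = rec["readmit_date"]
        if readmit is None or (isinstance(readmit, float) and np.isnan(readmit)) or pd.isna(readmit):
            keep.append(i)
            labels.append(False)
            continue
        delta = (readmit - rec["discharge_date"]).days
        if delta <= 0:
            rejects.append(Reject("patients", int(i), "readmit_date on or before discharge_date"))
            continue
        keep.append(i)
        labels.append(1 <= delta <= window_days)
    out = patients.loc[keep].copy()
    out["readmitted_30d"] = labels
    return out.reset_index(drop=True), rejects


def build_exposure_matrix(
    patients: pd.DataFrame, prescriptions: pd.DataFrame
) -> ExposureMatrix:
    """Binary incidence over normalized prescriptions.

    Duplicate prescriptions of one drug collapse to a single 1; UNMAPPED
    records are excluded; drug columns are ordered lexicographically.  A
    prescription for a patient absent from the patients table is a fatal
    referential-integrity error.
    """
    if "readmitted_30d" not in patients.columns:
        raise ValueError("patients must be labeled (run label_readmission first)")
    ids = patients["patient_id"].tolist()
    known = set(ids)
    bad = set(prescriptions["patient_id"]) - known
    if bad:
        raise ReferentialIntegrityError(
            f"prescriptions reference unknown patient(s): {sorted(bad)[:5]}"
        )
    rx = prescriptions[prescriptions["drug_id"] != UNMAPPED]
    drugs = sorted(set(rx["drug_id"]))
    col = {d: j for j, d in enumerate(drugs)}
    row = {p: i for i, p in enumerate(ids)}
    cells = np.zeros((len(ids), len(drugs)), dtype=np.int8)
    for p, d in zip(rx["patient_id"], rx["drug_id"]):
        cells[row[p], col[d]] = 1
    covariates = patients[["age", "sex"]].copy()
    covariates.index = ids
    strata = None
    if "race" in patients.columns:
        strata = pd.Series(patients["race"].values, index=ids, name="race")
    return ExposureMatrix(
        patients=ids,
        drugs=drugs,
        cells=cells,
        outcome=patients["readmitted_30d"].to_numpy(dtype=bool),
        covariates=covariates,
        strata=strata,
    )


def cohort_summary(patients: pd.DataFrame, prescriptions: pd.DataFrame) -> pd.DataFrame:
    """Per-group descriptives: n, %, mean age, % male, mean prescription
    records per patient, distinct drugs; plus a Welch test on per-patient
    prescription counts between groups.

    "Prescriptions per patient" counts prescription records (not distinct
    drugs); UNMAPPED records still count as prescriptions.
    """
    import warnings

    if "readmitted_30d" not in patients.columns:
        raise ValueError("patients must be labeled (run label_readmission first)")
    n_total = len(patients)
    rx_counts = prescriptions.groupby("patient_id").size()
    per_patient = patients["patient_id"].map(rx_counts).fillna(0).to_numpy(dtype=float)

    rows = {}
    group_counts = {}
    for label, mask in (
        ("readmitted", patients["readmitted_30d"].to_numpy(dtype=bool)),
        ("no_readmission", ~patients["readmitted_30d"].to_numpy(dtype=bool)),
    ):
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"group {label!r} has no patients")
            rows[label] = dict.fromkeys(
                ["n", "pct", "mean_age", "pct_male", "mean_prescriptions", "distinct_drugs"],
                np.nan,
            )
            rows[label]["n"] = 0
            group_counts[label] = np.array([])
            continue
        sub = patients[mask]
        sex_known = sub["sex"].isin(["male", "female"])
        pct_male = (
            100.0 * (sub["sex"] == "male").sum() / sex_known.sum() if sex_known.any() else np.nan
        )
        pids = set(sub["patient_id"])
        sub_rx = prescriptions[prescriptions["patient_id"].isin(pids)]
        distinct = sub_rx["drug_id"].replace("", np.nan).dropna()
        distinct = distinct[distinct != UNMAPPED]
        rows[label] = {
            "n": n,
            "pct": 100.0 * n / n_total if n_total else np.nan,
            "mean_age": float(sub["age"].mean()),
            "pct_male": float(pct_male),
            "mean_prescriptions": float(per_patient[mask].mean()),
            "distinct_drugs": int(distinct.nunique()),
        }
        group_counts[label] = per_patient[mask]

    summary = pd.DataFrame(rows).T
    summary.index.name = "group"
    x, y = group_counts["readmitted"], group_counts["no_readmission"]
    if x.size >= 2 and y.size >= 2:
        t, df, p = welch_t_test(x, y)
    else:
        t = df = p = np.nan
    summary.attrs["welch_prescriptions"] = {"t": t, "df": df, "p": p}
    return summary
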