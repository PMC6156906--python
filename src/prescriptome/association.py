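"""Per-drug (and per-drug-class) covariate-adjusted association scan.

One separation-robust Bayesian logistic model per drug — design
``[intercept, exposure, age, sex]`` — compiled into a table of odds ratios,
Wald confidence intervals, p-values and Benjamini-Hochberg q-values.  The
drug family and the class family are corrected separately and never mixed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .ingest import ExposureMatrix
from .stats import (
    PriorSpec,
    bh_adjust,
    fit_bayes_logistic,
    wald_or_ci,
    welch_t_test,
    wilson_interval,
)

__all__ = [
    "scan_drugs",
    "scan_classes",
    "count_prescription_burden",
    "read_drug_classes",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = [
    "drug_id", "family", "n_exposed", "n_exposed_cases", "n_exposed_controls",
    "or", "ci_lo", "ci_hi", "p", "q",
    "exposed_frac", "exposed_frac_lo", "exposed_frac_hi",
    "converged", "skipped_reason",
]


def _fit_one(
    y: np.ndarray,
    exposure: np.ndarray,
    covars: pd.DataFrame,
    prior: PriorSpec,
) -> tuple[float, float, float, float, bool]:
    """Fit outcome ~ exposure + age + sex for one drug/class.

    Rows with unknown sex are excluded; zero-variance covariates are dropped
    from the design with a warning.  Returns (OR, lo, hi, p, converged).
    """
    sex = covars["sex"].to_numpy()
    keep = np.isin(sex, ("male", "female"))
    y = y[keep]
    exposure = exposure[keep]
    age = covars["age"].to_numpy(dtype=float)[keep]
    male = (sex[keep] == "male").astype(float)

    cols = [np.ones_like(age), exposure.astype(float)]
    names = ["intercept", "exposure"]
    for cname, col in (("age", age), ("sex_male", male)):
        if np.unique(col).size < 2:
            warnings.warn(f"covariate {cname!r} has zero variance; dropped from design")
            continue
        cols.append(col)
        names.append(cname)
    X = np.column_stack(cols)
    fit = fit_bayes_logistic(y, X, prior, term_names=names)
    or_, lo, hi, p = wald_or_ci(fit, "exposure")
    return or_, lo, hi, p, fit.converged


def _scan(
    matrix: ExposureMatrix,
    columns: dict[str, np.ndarray],
    prior: PriorSpec,
    min_exposed: int,
    family: str,
) -> pd.DataFrame:
    y = matrix.outcome.astype(float)
    rows = []
    for name in sorted(columns):
        exp = columns[name].astype(np.int8)
        n_exposed = int(exp.sum())
        rec = {
            "drug_id": name,
            "family": family,
            "n_exposed": n_exposed,
            "n_exposed_cases": int(exp[matrix.outcome].sum()),
            "n_exposed_controls": int(exp[~matrix.outcome].sum()),
        }
        if n_exposed < min_exposed:
            rec["skipped_reason"] = f"exposed {n_exposed} < min_exposed {min_exposed}"
            rows.append(rec)
            continue
        or_, lo, hi, p, conv = _fit_one(y, exp, matrix.covariates, prior)
        frac_lo, frac_hi = wilson_interval(n_exposed, len(matrix.patients))
        rec.update(
            {
                "or": or_, "ci_lo": lo, "ci_hi": hi, "p": p,
                "exposed_frac": n_exposed / len(matrix.patients),
                "exposed_frac_lo": frac_lo, "exposed_frac_hi": frac_hi,
                "converged": conv, "skipped_reason": "",
            }
        )
        rows.append(rec)
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    fitted = out["skipped_reason"] == ""
    out.loc[fitted, "q"] = bh_adjust(out.loc[fitted, "p"].to_numpy())
    out = out.sort_values(
        ["q", "p", "drug_id"], kind="stable", na_position="last"
    ).reset_index(drop=True)
    out.attrs["family"] = family
    return out


def scan_drugs(
    matrix: ExposureMatrix,
    prior: PriorSpec | None = None,
    min_exposed: int = 5,
) -> pd.DataFrame:
    """Covariate-adjusted association scan over every drug in the matrix.

    Drugs with fewer than ``min_exposed`` exposed patients are reported with
    a ``skipped_reason`` and excluded from the BH family (untested
    hypotheses contribute no p-values).  Results sorted by (q, p).
    """
    prior = prior or PriorSpec()
    cols = {d: matrix.cells[:, j] for j, d in enumerate(matrix.drugs)}
    return _scan(matrix, cols, prior, min_exposed, family="drug")


def read_drug_classes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("drug_id", "class_code") if c not in df.columns]
    if missing:
        raise ValueError(f"drug class map missing column(s) {missing}")
    return df


def scan_classes(
    matrix: ExposureMatrix,
    class_map: pd.DataFrame,
    prior: PriorSpec | None = None,
    min_exposed: int = 5,
) -> pd.DataFrame:
    """Drug-class scan: a patient is exposed to a class iff exposed to any
    member drug.  Same model as :func:`scan_drugs`; separate BH family."""
    prior = prior or PriorSpec()
    cols: dict[str, np.ndarray] = {}
    present = set(matrix.drugs)
    for code, grp in class_map.groupby("class_code"):
        members = [d for d in grp["drug_id"] if d in present]
        if not members:
            warnings.warn(f"drug class {code!r} has no member drugs in the matrix; skipped")
            continue
        idx = [matrix.drugs.index(d) for d in members]
        cols[str(code)] = (matrix.cells[:, idx].sum(axis=1) > 0).astype(np.int8)
    return _scan(matrix, cols, prior, min_exposed, family="class")


def count_prescription_burden(
    patients: pd.DataFrame, prescriptions: pd.DataFrame
) -> dict:
    """Per-group mean prescription records per patient with a Welch test."""
    if "readmitted_30d" not in patients.columns:
        raise ValueError("patients must be labeled")
    rx_counts = prescriptions.groupby("patient_id").size()
    per_patient = patients["patient_id"].map(rx_counts).fillna(0).to_numpy(dtype=float)
    case = patients["readmitted_30d"].to_numpy(dtype=bool)
    x, y = per_patient[case], per_patient[~case]
    out = {
        "mean_cases": float(x.mean()) if x.size else float("nan"),
        "mean_controls": float(y.mean()) if y.size else float("nan"),
        "n_cases": int(x.size),
        "n_controls": int(y.size),
    }
    if x.size >= 2 and y.size >= 2:
        t, df, p = welch_t_test(x, y)
        out.update({"welch_t": t, "welch_df": df, "welch_p": p})
    else:
        out.update({"welch_t": float("nan"), "welch_df": float("nan"), "welch_p": float("nan")})
    return out
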