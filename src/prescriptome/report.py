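"""Human-readable markdown report over a results bundle.

Top-k tables of drugs by q, enriched terms per channel, comorbid pairs and
gene-set overlaps, with the conventional "< 2.2e-16" display floor.  Report
numbers are parsed back from the machine TSVs, never recomputed.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .stats import format_p

__all__ = ["build_report"]


def _table(df: pd.DataFrame, columns: list[str], k: int) -> str:
    if df.empty:
        return "_No findings._\n"
    sub = df.head(k)[columns].copy()
    for col in ("p", "q"):
        if col in sub.columns:
            sub[col] = sub[col].map(lambda v: format_p(float(v)) if pd.notna(v) else "")
    for col in sub.columns:
        if sub[col].dtype.kind == "f":
            sub[col] = sub[col].map(lambda v: f"{v:.3g}" if pd.notna(v) else "")
    header = "| " + " | ".join(sub.columns) + " |"
    sep = "|" + "---|" * len(sub.columns)
    rows = ["| " + " | ".join(str(v) for v in rec) + " |" for rec in sub.itertuples(index=False)]
    return "\n".join([header, sep, *rows]) + "\n"


def build_report(results_dir, out_path=None, k: int = 10) -> str:
    """Render the report; returns the markdown and optionally writes it."""
    d = Path(results_dir)
    summary_path = d / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(f"missing results bundle file: {summary_path}")
    with open(summary_path) as fh:
        s = json.load(fh)

    lines = ["# Prescriptome readmission analysis report", ""]
    lines += [
        "## Cohort",
        "",
        f"- Patients: {s['n_patients']} ({s['n_cases']} readmitted within 30 days, "
        f"{s['case_pct']:.2f}%; {s['n_controls']} not readmitted, {s['control_pct']:.2f}%)",
        f"- Mean age: cases {s['mean_age_cases']:.2f}, controls {s['mean_age_controls']:.2f}",
        f"- Percent male: cases {s['pct_male_cases']:.1f}%, controls {s['pct_male_controls']:.1f}%",
        f"- Mean prescriptions/patient: cases {s['mean_prescriptions_cases']:.2f}, "
        f"controls {s['mean_prescriptions_controls']:.2f} "
        f"(Welch p {format_p(s['welch_prescriptions']['p'])})",
        "",
    ]

    sections = [
        ("associations.tsv", "Drugs associated with 30-day readmission",
         ["drug_id", "n_exposed_cases", "n_exposed_controls", "or", "ci_lo", "ci_hi", "p", "q"]),
        ("enrichment_primary.tsv", "Primary side-effect enrichment",
         ["term_name", "n_term_cases", "n_term_controls", "or", "p", "q"]),
        ("enrichment_secondary.tsv", "Secondary (interaction-predicted) side-effect enrichment",
         ["term_name", "n_term_cases", "n_term_controls", "or", "p", "q"]),
        ("comorbidity.tsv", "Pairwise disease comorbidity",
         ["stratum", "disease_a", "disease_b", "or", "ci_lo", "ci_hi", "p", "q"]),
        ("overlaps.tsv", "Shared genetic architecture (gene-set overlap)",
         ["disease_a", "disease_b", "n_shared", "p", "q"]),
    ]
    for fname, title, cols in sections:
        path = d / fname
        lines += [f"## {title}", ""]
        if not path.exists():
            lines += ["_Stage not run._", ""]
            continue
        df = pd.read_csv(path, sep="\t")
        if "skipped_reason" in df.columns:
            df = df[df["skipped_reason"].isna() | (df["skipped_reason"] == "")]
        if "q" in df.columns:
            df = df.sort_values(["q", "p"], kind="stable", na_position="last")
        lines += [_table(df, [c for c in cols if c in df.columns], k), ""]

    text = "\n".join(lines)
    if out_path is not None:
        Path(out_path).write_text(text)
    return text
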