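#!/usr/bin/env python
"""Cohort descriptives: group sizes, demographics and prescription burden.

Reads results/data/, labels the 30-day outcome, and tabulates per-group n,
percentage, mean age, percent male, mean prescription records per patient
and distinct drug counts, with a Welch test on prescription counts.
Writes results/tables/cohort_summary.tsv.
"""

from pathlib import Path

from prescriptome.ingest import (
    cohort_summary,
    label_readmission,
    normalize_drugs,
    read_drug_map,
    read_emr_tables,
)
from prescriptome.stats import format_p

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    patients, prescriptions, _, rejects = read_emr_tables(ROOT / "data")
    prescriptions, n_unmapped = normalize_drugs(
        prescriptions, read_drug_map(ROOT / "data" / "drugmap.tsv")
    )
    patients, label_rejects = label_readmission(patients)
    summary = cohort_summary(patients, prescriptions)

    out = ROOT / "tables"
    out.mkdir(parents=True, exist_ok=True)
    summary.to_csv(out / "cohort_summary.tsv", sep="\t")

    print(summary.round(2).to_string())
    welch = summary.attrs["welch_prescriptions"]
    print(f"\nrejected rows: {len(rejects) + len(label_rejects)}; "
          f"unmapped prescriptions: {n_unmapped}")
    print(f"Welch test on prescription counts: t = {welch['t']:.2f}, "
          f"p {format_p(welch['p'])}")


if __name__ == "__main__":
    main()
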