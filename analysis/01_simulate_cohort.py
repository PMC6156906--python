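#!/usr/bin/env python
"""Generate the default synthetic EMR cohort and reference tables.

Writes the TSV/GMT inputs every later analysis step consumes to
results/data/: 1275 index psychiatric discharges (89 readmitted within 30
days), prescriptions over a 120-drug vocabulary with three planted
drug-outcome effects, diagnoses with two planted comorbidity pairs, and
format-compatible side-effect / interaction / gene-set references.
"""

from pathlib import Path

from prescriptome import CohortConfig, generate_cohort
from prescriptome.synthetic import generate_reference_tables, write_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    cfg = CohortConfig()  # the calibrated defaults, seed 20140901
    cohort = generate_cohort(cfg)
    refs = generate_reference_tables(cfg)
    written = write_cohort(cohort, OUT, refs)
    print(f"wrote {len(written)} files to {OUT}")
    print(f"patients: {len(cohort.patients)} "
          f"({int(cohort.patients['readmitted_30d'].sum())} readmitted)")
    print(f"prescription records: {len(cohort.prescriptions)}")
    for drug, t in cohort.truth["planted_drug_effects"].items():
        print(f"planted {drug}: OR {t['odds_ratio']:.2f}, "
              f"{t['n_exposed']} exposed patients")


if __name__ == "__main__":
    main()
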