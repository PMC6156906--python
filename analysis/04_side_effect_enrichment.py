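#!/usr/bin/env python
"""Primary and secondary side-effect enrichment.

Projects drug exposures onto single-drug adverse-event terms and
co-prescription pairs onto interaction-predicted terms, then tests per-term
enrichment between readmitted and non-readmitted patients (Fisher exact,
BH within channel).  Also tabulates the overlap between the two term
ontologies.  Writes results/tables/enrichment_{primary,secondary}.tsv.
"""

from pathlib import Path

from prescriptome.ingest import (
    build_exposure_matrix,
    label_readmission,
    normalize_drugs,
    read_drug_map,
    read_emr_tables,
)
from prescriptome.side_effects import (
    compare_term_ontologies,
    enrich_terms,
    project_primary,
    project_secondary,
    read_interaction_reference,
    read_side_effect_reference,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    data = ROOT / "data"
    patients, prescriptions, _, _ = read_emr_tables(data)
    prescriptions, _ = normalize_drugs(prescriptions, read_drug_map(data / "drugmap.tsv"))
    patients, _ = label_readmission(patients)
    matrix = build_exposure_matrix(patients, prescriptions)

    offsides = read_side_effect_reference(data / "offsides.tsv")
    twosides = read_interaction_reference(data / "twosides.tsv")
    out = ROOT / "tables"
    out.mkdir(parents=True, exist_ok=True)

    for channel, inc in (
        ("primary", project_primary(matrix, offsides)),
        ("secondary", project_secondary(matrix, twosides)),
    ):
        enr = enrich_terms(inc, matrix.outcome)
        enr.to_csv(out / f"enrichment_{channel}.tsv", sep="\t", index=False,
                   float_format="%.6g")
        informative = enr[~enr["degenerate"]]
        sig = informative[informative["q"] < 0.05]
        print(f"{channel}: {len(inc.terms)} terms projected, "
              f"{len(sig)} enriched at q < 0.05")
        cols = ["term_name", "n_term_cases", "n_term_controls", "or", "q"]
        print(sig.head(5)[cols].round(3).to_string(index=False), "\n")

    overlap = compare_term_ontologies({"offsides": offsides, "twosides": twosides})
    overlap.to_csv(out / "ontology_overlap.tsv", sep="\t", index=False)
    r = overlap.iloc[0]
    print(f"ontology overlap: {r['n_shared']} shared terms, "
          f"{r['n_only_a']} only in the single-drug reference, "
          f"{r['n_only_b']} only in the interaction reference")


if __name__ == "__main__":
    main()
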