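#!/usr/bin/env python
"""Digital comorbidity survey and shared genetic architecture.

Race-stratified pairwise disease odds ratios over the diagnosis data (with
network export of significant edges), followed by hypergeometric gene-set
overlap tests: first on the synthetic gene sets with planted overlaps, then
on the packaged curated psychiatric/cardiovascular gene modules.  Writes
results/tables/comorbidity.tsv and overlaps_*.tsv plus GraphML networks.
"""

from pathlib import Path

from prescriptome.comorbidity import (
    GeneSetCollection,
    build_diagnosis_incidence,
    comorbidity_scan,
    export_network,
    load_packaged_genesets,
    read_dx_map,
    shared_architecture_scan,
)
from prescriptome.ingest import label_readmission, read_emr_tables
from prescriptome.stats import format_p

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    data = ROOT / "data"
    patients, _, diagnoses, _ = read_emr_tables(data)
    patients, _ = label_readmission(patients)
    dx_map = read_dx_map(data / "dxmap.tsv")
    inc = build_diagnosis_incidence(diagnoses, patients, dx_map)

    out = ROOT / "tables"
    out.mkdir(parents=True, exist_ok=True)

    strata = sorted(s for s in inc.strata.unique() if s)
    com = comorbidity_scan(inc, strata)
    com.to_csv(out / "comorbidity.tsv", sep="\t", index=False, float_format="%.6g")
    export_network(com, ROOT / "networks", neuropsychiatric=inc.neuropsychiatric)

    pooled = comorbidity_scan(inc).set_index(["disease_a", "disease_b"])
    print("planted comorbidity pairs (pooled):")
    for pair in (("hypertension", "sleep_disorder"), ("coronary_artery_disease", "sleep_disorder")):
        r = pooled.loc[pair]
        print(f"  {pair[0]} + {pair[1]}: OR {r['or']:.2f} "
              f"({r['ci_lo']:.2f}-{r['ci_hi']:.2f}), p {format_p(r['p'])}")
    sig = com[com["q"] < 0.05]
    print(f"stratified scan: {len(com)} pairs tested, {len(sig)} with q < 0.05 "
          f"across {len(strata)} race strata\n")

    synth = GeneSetCollection.from_gmt(data / "genesets.gmt")
    ov = shared_architecture_scan(synth)
    ov.drop(columns="shared_genes").to_csv(out / "overlaps_synthetic.tsv", sep="\t",
                                           index=False, float_format="%.6g")
    top = ov.iloc[0]
    print(f"synthetic gene sets: strongest overlap {top['disease_a']} / "
          f"{top['disease_b']}: {top['n_shared']} shared genes, p {format_p(top['p'])}")

    curated = load_packaged_genesets()
    ov2 = shared_architecture_scan(curated)
    ov2.to_csv(out / "overlaps_curated.tsv", sep="\t", index=False, float_format="%.6g")
    r = ov2.set_index(["disease_a", "disease_b"]).loc[("bradycardia", "schizophrenia")]
    print(f"curated modules: bradycardia / schizophrenia share {r['n_shared']} genes "
          f"({r['shared_genes']}), p {format_p(r['p'])}")


if __name__ == "__main__":
    main()
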