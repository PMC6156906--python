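"""Pipeline orchestration: configuration, stage execution, manifest.

``run_pipeline`` wires ingest -> association -> side effects -> comorbidity
and genetics over a directory of TSV/GMT inputs and writes the machine
outputs (TSVs, summary.json, manifest.json).  Outputs are a pure function
of the inputs and the configuration: reruns on identical inputs are
byte-identical.  Logs go to standard error via ``logging``; data go to
files only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import count_prescription_burden, scan_drugs
from .comorbidity import (
    GeneSetCollection,
    build_diagnosis_incidence,
    comorbidity_scan,
    export_network,
    read_dx_map,
    shared_architecture_scan,
)
from .ingest import (
    build_exposure_matrix,
    cohort_summary,
    label_readmission,
    normalize_drugs,
    read_drug_map,
    read_emr_tables,
)
from .side_effects import (
    enrich_terms,
    project_primary,
    project_secondary,
    read_interaction_reference,
    read_side_effect_reference,
)
from .stats import PriorSpec

logger = logging.getLogger("prescriptome")

ALL_STAGES = ("ingest", "association", "side_effects", "comorbidity")


@dataclass
class RunConfig:
    input_dir: str
    out_dir: str
    prior: PriorSpec = field(default_factory=PriorSpec)
    min_exposed: int = 5
    fdr_threshold: float = 0.05
    window_days: int = 30
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    universe_size: int | None = None

    def validate(self) -> None:
        if not Path(self.input_dir).is_dir():
            raise FileNotFoundError(f"input directory not found: {self.input_dir}")
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ValueError("fdr_threshold must lie in (0, 1)")
        if self.min_exposed < 1:
            raise ValueError("min_exposed must be >= 1")
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        prior = raw.pop("prior", None)
        cfg = cls(**raw)
        if isinstance(prior, dict):
            cfg.prior = PriorSpec(**prior)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; returns the manifest dict."""
    config.validate()
    indir = Path(config.input_dir)
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    # filesystem locations are not part of the outputs' identity: input
    # content is pinned by the checksums below, not by path strings
    cfg_record = {
        k: v for k, v in config.to_dict().items() if k not in ("out_dir", "input_dir")
    }
    manifest: dict = {
        "tool": "prescriptome",
        "version": __version__,
        "config": cfg_record,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_record, sort_keys=True).encode()
        ).hexdigest(),
        "inputs": {},
        "row_counts": {},
        "warnings": [],
    }
    for f in sorted(indir.glob("*.tsv")) + sorted(indir.glob("*.gmt")):
        manifest["inputs"][f.name] = _sha256(f)

    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        # ---- ingest -------------------------------------------------------
        patients, prescriptions, diagnoses, rejects = read_emr_tables(indir)
        drug_map = read_drug_map(indir / "drugmap.tsv")
        prescriptions, n_unmapped = normalize_drugs(prescriptions, drug_map)
        if n_unmapped:
            logger.warning("%d prescription records UNMAPPED", n_unmapped)
        patients, label_rejects = label_readmission(patients, config.window_days)
        rejects = rejects + label_rejects
        matrix = build_exposure_matrix(patients, prescriptions)
        summary = cohort_summary(patients, prescriptions)
        manifest["row_counts"]["patients"] = len(patients)
        manifest["row_counts"]["prescriptions"] = len(prescriptions)
        manifest["row_counts"]["rejects"] = len(rejects)
        manifest["row_counts"]["unmapped_prescriptions"] = n_unmapped
        if rejects:
            _write_tsv(
                pd.DataFrame([dataclasses.asdict(r) for r in rejects]),
                outdir / "rejects.tsv",
            )

        results: dict = {"summary": summary}

        # ---- association --------------------------------------------------
        if "association" in config.stages:
            assoc = scan_drugs(matrix, config.prior, config.min_exposed)
            _write_tsv(assoc, outdir / "associations.tsv")
            manifest["row_counts"]["associations"] = len(assoc)
            results["associations"] = assoc
            results["burden"] = count_prescription_burden(patients, prescriptions)

        # ---- side effects -------------------------------------------------
        if "side_effects" in config.stages:
            offsides = read_side_effect_reference(indir / "offsides.tsv")
            twosides = read_interaction_reference(indir / "twosides.tsv")
            prim = project_primary(matrix, offsides)
            sec = project_secondary(matrix, twosides)
            enr_p = enrich_terms(prim, matrix.outcome)
            enr_s = enrich_terms(sec, matrix.outcome)
            _write_tsv(enr_p, outdir / "enrichment_primary.tsv")
            _write_tsv(enr_s, outdir / "enrichment_secondary.tsv")
            audit = pd.concat([prim.audit, sec.audit], ignore_index=True)
            _write_tsv(audit, outdir / "audit.tsv")
            manifest["row_counts"]["enrichment_primary"] = len(enr_p)
            manifest["row_counts"]["enrichment_secondary"] = len(enr_s)
            results["enrichment_primary"] = enr_p
            results["enrichment_secondary"] = enr_s

        # ---- comorbidity & genetics ---------------------------------------
        if "comorbidity" in config.stages:
            dx_map = read_dx_map(indir / "dxmap.tsv")
            inc = build_diagnosis_incidence(diagnoses, patients, dx_map)
            strata = sorted(s for s in inc.strata.unique() if s)
            com = comorbidity_scan(inc, strata or None)
            _write_tsv(com, outdir / "comorbidity.tsv")
            export_network(
                com,
                outdir / "networks",
                q_threshold=config.fdr_threshold,
                neuropsychiatric=inc.neuropsychiatric,
            )
            manifest["row_counts"]["comorbidity"] = len(com)
            results["comorbidity"] = com
            gmt = indir / "genesets.gmt"
            if gmt.exists():
                gs = GeneSetCollection.from_gmt(gmt)
                ov = shared_architecture_scan(gs, universe_size=config.universe_size)
                _write_tsv(ov, outdir / "overlaps.tsv")
                manifest["row_counts"]["overlaps"] = len(ov)
                results["overlaps"] = ov

        caught = sorted({str(w.message) for w in wrec})

    manifest["warnings"] = caught

    case_row = summary.loc["readmitted"]
    ctrl_row = summary.loc["no_readmission"]
    summary_json = {
        "n_patients": int(case_row["n"] + ctrl_row["n"]),
        "n_cases": int(case_row["n"]),
        "n_controls": int(ctrl_row["n"]),
        "case_pct": float(case_row["pct"]),
        "control_pct": float(ctrl_row["pct"]),
        "mean_age_cases": float(case_row["mean_age"]),
        "mean_age_controls": float(ctrl_row["mean_age"]),
        "pct_male_cases": float(case_row["pct_male"]),
        "pct_male_controls": float(ctrl_row["pct_male"]),
        "mean_prescriptions_cases": float(case_row["mean_prescriptions"]),
        "mean_prescriptions_controls": float(ctrl_row["mean_prescriptions"]),
        "distinct_drugs_cases": int(case_row["distinct_drugs"]),
        "distinct_drugs_controls": int(ctrl_row["distinct_drugs"]),
        "welch_prescriptions": summary.attrs["welch_prescriptions"],
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary_json, fh, indent=1, sort_keys=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    manifest["results"] = results
    return manifest
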