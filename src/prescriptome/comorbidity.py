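"""Digital comorbidity survey and shared genetic architecture.

Pairwise disease co-occurrence over EMR diagnosis data, summarized as
Haldane-corrected odds ratios with Fisher exact p-values (optionally
stratified, e.g. by race), exportable as a disease network; and
hypergeometric upper-tail tests of gene-set overlap between disease
phenotypes against a finite gene universe.

The hypergeometric universe defaults to the union of all genes in the
loaded collection; it can be overridden with a fixed genome-scale constant,
which materially changes the tail probabilities (the overlap counts do not
change).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import ContingencyTable2x2, bh_adjust, fisher_exact_2x2, hypergeom_tail

__all__ = [
    "DiagnosisIncidence",
    "GeneSetCollection",
    "read_dx_map",
    "build_diagnosis_incidence",
    "comorbidity_scan",
    "shared_architecture_scan",
    "export_network",
    "load_packaged_genesets",
    "COMORBIDITY_COLUMNS",
]

COMORBIDITY_COLUMNS = [
    "stratum", "disease_a", "disease_b",
    "n_both", "n_a_only", "n_b_only", "n_neither",
    "or", "ci_lo", "ci_hi", "p", "q",
]


@dataclass
class DiagnosisIncidence:
    patients: list[str]
    diseases: list[str]                    # lexicographic
    cells: np.ndarray                      # (n_patients, n_diseases) binary
    strata: pd.Series                      # per-patient stratum label
    neuropsychiatric: dict[str, bool]

    def column(self, disease: str) -> np.ndarray:
        return self.cells[:, self.diseases.index(disease)]


@dataclass(frozen=True)
class GeneSetCollection:
    """Disease -> gene-symbol sets over a finite universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes <= self.universe:
                raise ValueError(f"gene set {name!r} is not a subset of the universe")

    @classmethod
    def from_gmt(cls, path, universe: set[str] | None = None) -> "GeneSetCollection":
        """Read standard GMT (name <tab> description <tab> genes...); symbols
        are uppercased and deduplicated.  Universe defaults to the union."""
        sets: dict[str, frozenset[str]] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not parts[0]:
                    continue
                genes = frozenset(g.strip().upper() for g in parts[2:] if g.strip())
                sets[parts[0]] = genes
        uni = frozenset(universe) if universe is not None else frozenset().union(*sets.values(), frozenset())
        return cls(sets=sets, universe=uni)

    def to_gmt(self, path, descriptions: dict[str, str] | None = None) -> None:
        descriptions = descriptions or {}
        with open(path, "w") as fh:
            for name in sorted(self.sets):
                genes = "\t".join(sorted(self.sets[name]))
                fh.write(f"{name}\t{descriptions.get(name, 'na')}\t{genes}\n")


def load_packaged_genesets() -> GeneSetCollection:
    """Curated psychiatric/cardiovascular disease gene sets shipped with the
    package (literature-derived shared gene modules)."""
    path = resources.files("prescriptome") / "data" / "disease_genesets.gmt"
    return GeneSetCollection.from_gmt(str(path))


def read_dx_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("dx_code", "disease_id") if c not in df.columns]
    if missing:
        raise ValueError(f"dx map missing column(s) {missing}")
    if "neuropsychiatric_flag" not in df.columns:
        df = df.assign(neuropsychiatric_flag="0")
    return df


def build_diagnosis_incidence(
    diagnoses: pd.DataFrame,
    patients: pd.DataFrame,
    dx_map: pd.DataFrame,
) -> DiagnosisIncidence:
    """Group raw dx codes into disease concepts; repeated codes collapse to a
    single 1; unmapped codes are excluded (count kept in the audit attrs)."""
    mapping = dict(zip(dx_map["dx_code"], dx_map["disease_id"]))
    neuro = {
        d: str(f).strip() in ("1", "true", "True")
        for d, f in zip(dx_map["disease_id"], dx_map.get("neuropsychiatric_flag", []))
    }
    ids = patients["patient_id"].tolist()
    row = {p: i for i, p in enumerate(ids)}
    diseases = sorted(set(mapping.values()))
    col = {d: j for j, d in enumerate(diseases)}
    cells = np.zeros((len(ids), len(diseases)), dtype=np.int8)
    n_unmapped = 0
    for p, code in zip(diagnoses["patient_id"], diagnoses["dx_code"]):
        d = mapping.get(code)
        if d is None:
            n_unmapped += 1
            continue
        i = row.get(p)
        if i is not None:
            cells[row[p], col[d]] = 1
    strata = pd.Series(
        patients["race"].values if "race" in patients.columns else [""] * len(ids),
        index=ids,
        name="stratum",
    )
    inc = DiagnosisIncidence(
        patients=ids, diseases=diseases, cells=cells, strata=strata, neuropsychiatric=neuro
    )
    empty = [d for d in diseases if inc.column(d).sum() == 0]
    if empty:
        warnings.warn(f"diseases with no diagnosed patients: {empty}")
    if n_unmapped:
        warnings.warn(f"{n_unmapped} diagnosis rows had unmapped dx codes")
    return inc


def _pair_result(x: np.ndarray, y: np.ndarray) -> dict:
    a = int((x & y).sum())          # both
    b = int((x & ~y).sum())         # A only
    c = int((~x & y).sum())         # B only
    d = int((~x & ~y).sum())        # neither
    p, orr = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
    # Wald CI on the Haldane-corrected log OR (Woolf with 0.5 correction if needed)
    aa, bb, cc, dd = (v + 0.5 if min(a, b, c, d) == 0 else v for v in (a, b, c, d))
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    z = sps.norm.ppf(0.975)
    log_or = np.log(orr)
    return {
        "n_both": a, "n_a_only": b, "n_b_only": c, "n_neither": d,
        "or": orr, "ci_lo": float(np.exp(log_or - z * se)),
        "ci_hi": float(np.exp(log_or + z * se)), "p": p,
    }


def comorbidity_scan(
    incidence: DiagnosisIncidence,
    strata: list[str] | None = None,
) -> pd.DataFrame:
    """Fisher/Haldane odds ratios for every unordered disease pair, within
    each requested stratum (default: one pooled stratum labelled "all").
    BH is applied within stratum; pairs are emitted in canonical order."""
    results = []
    if strata is None:
        groups = [("all", np.ones(len(incidence.patients), dtype=bool))]
    else:
        labels = incidence.strata.to_numpy()
        groups = [(s, labels == s) for s in strata]
    for stratum, mask in groups:
        if mask.sum() == 0:
            warnings.warn(f"stratum {stratum!r} has no patients; skipped")
            continue
        sub = incidence.cells[mask].astype(bool)
        rows = []
        for ja, jb in combinations(range(len(incidence.diseases)), 2):
            da, db = incidence.diseases[ja], incidence.diseases[jb]
            rec = {"stratum": stratum, "disease_a": da, "disease_b": db}
            rec.update(_pair_result(sub[:, ja], sub[:, jb]))
            rows.append(rec)
        df = pd.DataFrame(rows, columns=[c for c in COMORBIDITY_COLUMNS if c != "q"])
        df["q"] = bh_adjust(df["p"].to_numpy()) if len(df) else np.nan
        results.append(df[COMORBIDITY_COLUMNS])
    if not results:
        return pd.DataFrame(columns=COMORBIDITY_COLUMNS)
    return pd.concat(results, ignore_index=True)


def shared_architecture_scan(
    genesets: GeneSetCollection,
    pairs: list[tuple[str, str]] | None = None,
    universe_size: int | None = None,
) -> pd.DataFrame:
    """Hypergeometric upper-tail overlap test for disease gene-set pairs.

    ``universe_size`` overrides the collection's universe size (the overlap
    and set sizes are unchanged); BH across the tested pairs.
    """
    if pairs is None:
        pairs = list(combinations(sorted(genesets.sets), 2))
    for pair in pairs:
        for d in pair:
            if d not in genesets.sets:
                raise KeyError(f"disease {d!r} not in the gene-set collection")
    N = universe_size if universe_size is not None else len(genesets.universe)
    rows = []
    for da, db in pairs:
        sa, sb = genesets.sets[da], genesets.sets[db]
        shared = sorted(sa & sb)
        rows.append(
            {
                "disease_a": da,
                "disease_b": db,
                "n_set_a": len(sa),
                "n_set_b": len(sb),
                "n_shared": len(shared),
                "shared_genes": ",".join(shared),
                "p": hypergeom_tail(N, len(sa), len(sb), len(shared)),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["disease_a", "disease_b", "n_set_a", "n_set_b", "n_shared", "shared_genes", "p"],
    )
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else np.nan
    return out.sort_values(["p", "disease_a", "disease_b"], kind="stable").reset_index(drop=True)


def export_network(
    results: pd.DataFrame,
    directory,
    *,
    q_threshold: float = 0.05,
    neuropsychiatric: dict[str, bool] | None = None,
    fmt: str = "graphml",
) -> dict[str, nx.Graph]:
    """One disease graph per stratum: nodes are diseases (with a
    neuropsychiatric flag), edges are pairs with q below the threshold,
    weighted by the odds ratio.  Writes GraphML or edge-list TSV per stratum
    and returns the graphs."""
    from pathlib import Path

    if fmt not in {"graphml", "tsv"}:
        raise ValueError("fmt must be 'graphml' or 'tsv'")
    neuropsychiatric = neuropsychiatric or {}
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    graphs: dict[str, nx.Graph] = {}
    strata = results["stratum"].unique() if len(results) else []
    for stratum in strata:
        sub = results[results["stratum"] == stratum]
        g = nx.Graph(name=str(stratum))
        diseases = sorted(set(sub["disease_a"]) | set(sub["disease_b"]))
        for d in diseases:
            g.add_node(d, neuropsychiatric=bool(neuropsychiatric.get(d, False)))
        sig = sub[sub["q"] < q_threshold]
        for _, r in sig.iterrows():
            g.add_edge(r["disease_a"], r["disease_b"], weight=float(r["or"]), q=float(r["q"]))
        graphs[str(stratum)] = g
        if fmt == "graphml":
            nx.write_graphml(g, out / f"comorbidity_{stratum}.graphml")
        else:
            rows = [
                {"disease_a": a, "disease_b": b, "weight": d["weight"], "q": d["q"]}
                for a, b, d in g.edges(data=True)
            ]
            pd.DataFrame(rows, columns=["disease_a", "disease_b", "weight", "q"]).to_csv(
                out / f"comorbidity_{stratum}.tsv", sep="\t", index=False, lineterminator="\n"
            )
    return graphs
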