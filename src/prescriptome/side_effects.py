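"""Side-effect projection and enrichment.

Primary channel: a patient carries an adverse-event term if prescribed at
least one drug the single-drug reference links to that term.  Secondary
channel: a patient carries a term if at least one unordered pair of their
co-prescribed drugs maps to it in the drug-pair interaction reference.
Per-term enrichment between readmitted and non-readmitted patients is a
patient-level 2x2 Fisher exact test with a Haldane-corrected odds ratio;
BH correction is applied within each channel separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .ingest import ExposureMatrix
from .stats import ContingencyTable2x2, bh_adjust, fisher_exact_2x2

__all__ = [
    "TermIncidence",
    "read_side_effect_reference",
    "read_interaction_reference",
    "project_primary",
    "enumerate_pairs",
    "project_secondary",
    "enrich_terms",
    "compare_term_ontologies",
    "ENRICHMENT_COLUMNS",
]

ENRICHMENT_COLUMNS = [
    "term_id", "term_name", "channel",
    "n_term_cases", "n_term_controls", "n_noterm_cases", "n_noterm_controls",
    "or", "p", "q", "degenerate",
]


@dataclass
class TermIncidence:
    """Binary patients x terms matrix with an audit trail of contributors."""

    patients: list[str]
    terms: list[str]                 # term ids, lexicographic
    term_names: dict[str, str]
    cells: np.ndarray                # (n_patients, n_terms) in {0, 1}
    channel: str                     # "primary" | "secondary"
    audit: pd.DataFrame              # patient_id, term_id, source (drug or "a+b")

    def prevalence(self) -> pd.Series:
        return pd.Series(self.cells.mean(axis=0), index=self.terms)


def read_side_effect_reference(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("drug_id", "term_id", "term_name") if c not in df.columns]
    if missing:
        raise ValueError(f"side-effect reference missing column(s) {missing}")
    if df["term_id"].eq("").any():
        raise ValueError("side-effect reference has empty term ids")
    return df.drop_duplicates(["drug_id", "term_id"]).reset_index(drop=True)


def read_interaction_reference(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("drug_a", "drug_b", "term_id", "term_name") if c not in df.columns]
    if missing:
        raise ValueError(f"interaction reference missing column(s) {missing}")
    if "severity" not in df.columns:
        df = df.assign(severity="")
    # canonical unordered pair: drug_a < drug_b
    a = df[["drug_a", "drug_b"]].min(axis=1)
    b = df[["drug_a", "drug_b"]].max(axis=1)
    df = df.assign(drug_a=a, drug_b=b)
    return df.drop_duplicates(["drug_a", "drug_b", "term_id"]).reset_index(drop=True)


def project_primary(matrix: ExposureMatrix, ref: pd.DataFrame) -> TermIncidence:
    """Patient has a term iff exposed to >= 1 drug carrying it (set union)."""
    term_names = dict(zip(ref["term_id"], ref["term_name"]))
    terms = sorted(set(ref["term_id"]))
    tcol = {t: j for j, t in enumerate(terms)}
    dcol = {d: j for j, d in enumerate(matrix.drugs)}
    # drug x term indicator restricted to drugs present in the matrix
    ind = np.zeros((len(matrix.drugs), len(terms)), dtype=np.int8)
    n_absent = 0
    audit_rows = []
    for d, t in zip(ref["drug_id"], ref["term_id"]):
        j = dcol.get(d)
        if j is None:
            n_absent += 1
            continue
        ind[j, tcol[t]] = 1
    cells = (matrix.cells @ ind > 0).astype(np.int8)
    # audit: contributing drugs per (patient, term)
    pi, dj = np.nonzero(matrix.cells)
    for i, j in zip(pi, dj):
        for t in np.flatnonzero(ind[j]):
            audit_rows.append((matrix.patients[i], terms[t], matrix.drugs[j]))
    audit = pd.DataFrame(audit_rows, columns=["patient_id", "term_id", "source"])
    inc = TermIncidence(
        patients=list(matrix.patients),
        terms=terms,
        term_names=term_names,
        cells=cells,
        channel="primary",
        audit=audit,
    )
    inc.audit.attrs["n_ref_rows_without_matrix_drug"] = n_absent
    return inc


def enumerate_pairs(row: np.ndarray, drugs: list[str]) -> list[tuple[str, str]]:
    """All C(k, 2) unordered co-prescription pairs of one exposure row, in
    canonical (lexicographic) order."""
    exposed = sorted(drugs[j] for j in np.flatnonzero(np.asarray(row)))
    return list(combinations(exposed, 2))


def project_secondary(matrix: ExposureMatrix, ref: pd.DataFrame) -> TermIncidence:
    """Patient has a term iff >= 1 of their co-prescription pairs maps to it."""
    pair_terms: dict[tuple[str, str], list[str]] = {}
    term_names = dict(zip(ref["term_id"], ref["term_name"]))
    for a, b, t in zip(ref["drug_a"], ref["drug_b"], ref["term_id"]):
        key = (a, b) if a <= b else (b, a)
        pair_terms.setdefault(key, []).append(t)
    terms = sorted(set(ref["term_id"]))
    tcol = {t: j for j, t in enumerate(terms)}
    cells = np.zeros((len(matrix.patients), len(terms)), dtype=np.int8)
    audit_rows = []
    for i, pid in enumerate(matrix.patients):
        for pair in enumerate_pairs(matrix.cells[i], matrix.drugs):
            for t in pair_terms.get(pair, ()):
                cells[i, tcol[t]] = 1
                audit_rows.append((pid, t, f"{pair[0]}+{pair[1]}"))
    audit = pd.DataFrame(audit_rows, columns=["patient_id", "term_id", "source"])
    return TermIncidence(
        patients=list(matrix.patients),
        terms=terms,
        term_names=term_names,
        cells=cells,
        channel="secondary",
        audit=audit,
    )


def enrich_terms(incidence: TermIncidence, outcome: np.ndarray) -> pd.DataFrame:
    """Per-term patient-level 2x2 enrichment (case vs control).

    Terms present in all or no patients are retained with p = 1 and a
    ``degenerate`` flag.  BH within the incidence's channel; sorted by q.
    """
    outcome = np.asarray(outcome, dtype=bool)
    if outcome.shape[0] != len(incidence.patients):
        raise ValueError("outcome length must match incidence patients")
    n_cases = int(outcome.sum())
    n_controls = int((~outcome).sum())
    rows = []
    for j, term in enumerate(incidence.terms):
        pos = incidence.cells[:, j].astype(bool)
        a = int((pos & outcome).sum())
        b = int((pos & ~outcome).sum())
        c, d = n_cases - a, n_controls - b
        degenerate = (a + b == 0) or (c + d == 0)
        if degenerate:
            p, orr = 1.0, float("nan")
        else:
            p, orr = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
        rows.append(
            {
                "term_id": term,
                "term_name": incidence.term_names.get(term, term),
                "channel": incidence.channel,
                "n_term_cases": a, "n_term_controls": b,
                "n_noterm_cases": c, "n_noterm_controls": d,
                "or": orr, "p": p, "degenerate": degenerate,
            }
        )
    out = pd.DataFrame(rows, columns=[c for c in ENRICHMENT_COLUMNS if c != "q"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else np.nan
    out = out[ENRICHMENT_COLUMNS]
    out = out.sort_values(["q", "p", "term_id"], kind="stable").reset_index(drop=True)
    out.attrs["family"] = incidence.channel
    return out


def compare_term_ontologies(
    refs: dict[str, pd.DataFrame] | list[pd.DataFrame],
) -> pd.DataFrame:
    """Pairwise term-set overlaps across >= 2 references sharing a term-id
    space; terms present in only one source are the NA-style counts."""
    if isinstance(refs, list):
        refs = {f"ref{i + 1}": r for i, r in enumerate(refs)}
    if len(refs) < 2:
        raise ValueError("need at least two references to compare")
    sets = {name: set(df["term_id"]) for name, df in refs.items()}
    rows = []
    names = sorted(sets)
    for a, b in combinations(names, 2):
        rows.append(
            {
                "source_a": a,
                "source_b": b,
                "n_terms_a": len(sets[a]),
                "n_terms_b": len(sets[b]),
                "n_shared": len(sets[a] & sets[b]),
                "n_only_a": len(sets[a] - sets[b]),
                "n_only_b": len(sets[b] - sets[a]),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_union_all"] = len(set().union(*sets.values()))
    out.attrs["n_shared_all"] = len(set.intersection(*map(set, sets.values())))
    return out
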