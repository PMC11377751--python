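"""Interaction-table filtering for DDR-adjacent candidate discovery.

From a table of protein-protein interactions, keep the pairs that join one
DNA-repair-annotated protein to a partner carrying neither DDR annotation
(the candidate), require experimental support in at least two publications,
and drop candidates on housekeeping or recurrent-contaminant lists.  The
filter order is fixed (asymmetry -> evidence -> lists) so the per-stage
attrition funnel is reproducible, although the surviving set is
order-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .ontology import DNA_REPAIR, DNA_DAMAGE_RESPONSE

EVIDENCE_TYPES = ("experimental", "orthology", "predicted")


@dataclass(frozen=True)
class InteractionRecord:
    protein_a: str
    protein_b: str
    evidence_types: frozenset
    n_publications_experimental: int = 0

    def __post_init__(self):
        if self.protein_a == self.protein_b:
            raise ValueError("self-interaction records are not allowed")
        if self.n_publications_experimental < 0:
            raise ValueError("publication count must be >= 0")
        unknown = set(self.evidence_types) - set(EVIDENCE_TYPES)
        if unknown:
            raise ValueError(f"unknown evidence types: {sorted(unknown)}")

    def canonical(self) -> "InteractionRecord":
        if self.protein_a <= self.protein_b:
            return self
        return InteractionRecord(self.protein_b, self.protein_a,
                                 self.evidence_types,
                                 self.n_publications_experimental)


def dedupe_records(records) -> list[InteractionRecord]:
    """Canonicalize (a,b)/(b,a) duplicates by sorted id; first record wins."""
    seen: dict[tuple, InteractionRecord] = {}
    for rec in records:
        c = rec.canonical()
        key = (c.protein_a, c.protein_b)
        if key not in seen:
            seen[key] = c
    return list(seen.values())


def _is_candidate_side(terms: set) -> bool:
    return DNA_REPAIR not in terms and DNA_DAMAGE_RESPONSE not in terms


def filter_ddr_asymmetry(records, annots):
    """Keep pairs with DNA repair on exactly one side and no DDR on the other.

    A pair survives iff one protein carries the DNA repair term and the other
    carries neither the DNA repair nor the DNA damage response term; the
    DDR-naive side is recorded as the candidate.  Annotations must already be
    propagated.  Returns ``[(record, candidate_id), ...]``.
    """
    out = []
    for rec in records:
        ta = annots.get(rec.protein_a, set())
        tb = annots.get(rec.protein_b, set())
        if DNA_REPAIR in ta and _is_candidate_side(tb):
            out.append((rec, rec.protein_b))
        elif DNA_REPAIR in tb and _is_candidate_side(ta):
            out.append((rec, rec.protein_a))
    return out


def filter_evidence(tagged_records):
    """Require experimental evidence and at least two experimental publications."""
    return [(rec, cand) for rec, cand in tagged_records
            if "experimental" in rec.evidence_types
            and rec.n_publications_experimental >= 2]


def filter_lists(tagged_records, housekeeping_ids, contaminant_ids):
    """Drop pairs whose candidate is housekeeping or a recurrent contaminant.

    Returns ``(surviving tagged records, candidate id list)``; candidates are
    deduplicated and sorted, to be flagged as PPI-derived downstream.
    """
    hk, cont = set(housekeeping_ids), set(contaminant_ids)
    kept = [(rec, cand) for rec, cand in tagged_records
            if cand not in hk and cand not in cont]
    candidates = sorted({cand for _, cand in kept})
    return kept, candidates


def run_ppi_filter(records, annots, housekeeping_ids, contaminant_ids):
    """Full protocol with per-stage attrition counts.

    Returns ``(candidates, surviving records, attrition dict)``.
    """
    records = dedupe_records(records)
    attrition = {"input": len(records)}
    tagged = filter_ddr_asymmetry(records, annots)
    attrition["after_asymmetry"] = len(tagged)
    tagged = filter_evidence(tagged)
    attrition["after_evidence"] = len(tagged)
    tagged, candidates = filter_lists(tagged, housekeeping_ids, contaminant_ids)
    attrition["after_lists"] = len(tagged)
    attrition["candidates"] = len(candidates)
    return candidates, tagged, attrition


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.protein_a, r.protein_b, ";".join(sorted(r.evidence_types)),
          r.n_publications_experimental) for r in records],
        columns=["protein_a", "protein_b", "evidence_types",
                 "n_publications_experimental"])


def read_interactions_tsv(path) -> list[InteractionRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str})
    out = []
    for _, row in df.iterrows():
        ev = frozenset(t for t in str(row["evidence_types"]).split(";") if t)
        out.append(InteractionRecord(row["protein_a"], row["protein_b"], ev,
                                     int(row["n_publications_experimental"])))
    return out


def write_interactions_tsv(records, path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)
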