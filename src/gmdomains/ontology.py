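"""GO-based compilation of the genome-maintenance candidate universe.

Proteins are compiled by pooling, across species, everything annotated with
one of four genome-maintenance GO terms — DNA repair, DNA damage response,
cytokinesis, mitotic cell cycle — after propagating each term of interest to
proteins that carry only one of its descendant (child) terms.  Only ``is_a``
edges are traversed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

#: GO term ids for the four pooled genome-maintenance terms.
DNA_REPAIR = "GO:0006281"
DNA_DAMAGE_RESPONSE = "GO:0006974"
CYTOKINESIS = "GO:0000910"
MITOTIC_CELL_CYCLE = "GO:0000278"

DEFAULT_TERMS_OF_INTEREST = (DNA_REPAIR, DNA_DAMAGE_RESPONSE,
                             CYTOKINESIS, MITOTIC_CELL_CYCLE)

#: The two DDR terms driving the interaction-pair asymmetry filter.
DDR_TERMS = (DNA_REPAIR, DNA_DAMAGE_RESPONSE)


@dataclass
class GODag:
    """A rooted, acyclic ``is_a`` hierarchy of GO terms.

    ``parents`` maps each term to its set of is_a parents.  Internally a
    networkx DiGraph with child -> parent edges is kept for reachability.
    """

    parents: dict[str, set[str]]
    _graph: nx.DiGraph = field(init=False, repr=False)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for child, ps in self.parents.items():
            for p in ps:
                if p not in self.parents:
                    raise ValueError(f"parent {p!r} of {child!r} is not a term")
                g.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("GO DAG contains a cycle")
        self._graph = g

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    @classmethod
    def from_edges(cls, edges) -> "GODag":
        parents: dict[str, set[str]] = {}
        for child, parent in edges:
            parents.setdefault(child, set()).add(parent)
            parents.setdefault(parent, set())
        return cls(parents)

    @classmethod
    def from_tsv(cls, path) -> "GODag":
        """Read a (term_id, parent_id) table; empty parent marks a root."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        parents: dict[str, set[str]] = {}
        for term, parent in zip(df.iloc[:, 0], df.iloc[:, 1]):
            parents.setdefault(term, set())
            if parent:
                parents[term].add(parent)
                parents.setdefault(parent, set())
        return cls(parents)

    def to_tsv(self, path) -> None:
        rows = []
        for term in sorted(self.parents):
            ps = sorted(self.parents[term])
            if ps:
                rows.extend((term, p) for p in ps)
            else:
                rows.append((term, ""))
        pd.DataFrame(rows, columns=["term_id", "parent_id"]).to_csv(
            path, sep="\t", index=False)


AnnotationSet = dict  # protein id -> set of directly assigned GO term ids


def read_annotations(path) -> AnnotationSet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    annots: AnnotationSet = {}
    for pid, term in zip(df.iloc[:, 0], df.iloc[:, 1]):
        annots.setdefault(pid, set()).add(term)
    return annots


def write_annotations(annots: AnnotationSet, path) -> None:
    rows = [(pid, t) for pid in sorted(annots) for t in sorted(annots[pid])]
    pd.DataFrame(rows, columns=["protein_id", "term_id"]).to_csv(
        path, sep="\t", index=False)


def descendants(dag: GODag, term: str) -> set[str]:
    """All terms below ``term`` (transitive closure of the child relation).

    The term itself is excluded.  Raises ``KeyError`` for unknown terms.
    """
    if term not in dag:
        raise KeyError(f"unknown GO term {term!r}")
    # child -> parent edges: descendants of t are the ancestors of t in _graph
    # reversed, i.e. nodes from which t is reachable.
    return set(nx.ancestors(dag._graph, term))


def propagate_interest_terms(annots: AnnotationSet, dag: GODag,
                             terms=DEFAULT_TERMS_OF_INTEREST) -> AnnotationSet:
    """Add each term of interest to proteins annotated with any descendant.

    A protein directly annotated only with a child term of, say, DNA repair
    gains the DNA repair term itself; nothing is ever removed, and applying
    the operation twice equals applying it once.
    """
    desc = {t: descendants(dag, t) for t in terms if t in dag}
    out: AnnotationSet = {}
    for pid, ts in annots.items():
        new = set(ts)
        for t, d in desc.items():
            if new & d:
                new.add(t)
        out[pid] = new
    return out


@dataclass(frozen=True)
class ProteinRecord:
    """A compiled candidate with provenance."""

    protein_id: str
    species: str = ""
    go_terms: frozenset = frozenset()
    provenance: str = "GO"
    sequence: str = ""


def compile_gm_set(per_species_annots: dict[str, AnnotationSet], dag: GODag,
                   terms=DEFAULT_TERMS_OF_INTEREST,
                   propagate: bool = True) -> list[ProteinRecord]:
    """Pool, across species, all proteins annotated with a term of interest.

    Annotations are propagated first (configurable), then the union over
    species is deduplicated by protein id.  The output is sorted by protein
    id, hence invariant to species ordering.
    """
    seen: dict[str, ProteinRecord] = {}
    for species in sorted(per_species_annots):
        annots = per_species_annots[species]
        if propagate:
            annots = propagate_interest_terms(annots, dag, terms)
        for pid in sorted(annots):
            ts = annots[pid]
            hit = ts.intersection(terms)
            if hit and pid not in seen:
                seen[pid] = ProteinRecord(protein_id=pid, species=species,
                                          go_terms=frozenset(ts),
                                          provenance="GO")
    return [seen[pid] for pid in sorted(seen)]


def records_to_tsv(records, path) -> None:
    pd.DataFrame(
        [(r.protein_id, r.species, ";".join(sorted(r.go_terms)), r.provenance)
         for r in records],
        columns=["protein_id", "species", "go_terms", "provenance"],
    ).to_csv(path, sep="\t", index=False)
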