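"""Synthetic data generators with full ground truth.

Everything the discovery pipeline consumes can be simulated here: homologous
domain families at controlled divergence planted into decoy proteins,
coiled-coil and low-complexity tracts, GO DAGs and annotations, interaction
tables with evidence metadata, and per-tissue expression matrices with known
correlated modules.  Every generator is a pure function of its spec and an
explicit integer seed; every planted object is recorded machine-readably so
recovery can be scored against truth.

The divergence model is deliberately minimal: each family member derives from
a random ancestor by i.i.d. per-site substitution (probability
``1 - target_identity``, replacement drawn from the background composition,
so a fraction of substitutions silently restore the ancestral residue) and by
geometric-length indels placed uniformly.  No site-rate heterogeneity and no
tree-aware evolution are modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS, UNIFORM_BACKGROUND, random_sequence
from .msa import MSA
from .ontology import (AnnotationSet, DEFAULT_TERMS_OF_INTEREST, GODag)

HYDROPHOBIC = "LIVMF"
POLAR_HEPTAD = "EKQARSND"


# ---------------------------------------------------------------------------
# Domain families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one planted homologous domain family.

    ``target_identity`` is the expected fraction of sites at which a member
    still carries the ancestral residue before accounting for back-
    substitutions (a replacement drawn from the background can restore the
    ancestral residue, adding roughly ``(1-t) * f_max`` identity).
    ``indel_rate`` is the expected number of indel events per ancestor site.
    """

    family_id: str
    domain_length: int = 100
    n_members: int = 30
    target_identity: float = 0.4
    indel_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.domain_length < 10:
            raise ValueError("domain_length must be >= 10")
        if not (0.0 < self.target_identity <= 1.0):
            raise ValueError("target_identity must be in (0, 1]")
        if self.n_members < 2:
            raise ValueError("n_members must be >= 2")
        if self.indel_rate < 0:
            raise ValueError("indel_rate must be >= 0")


@dataclass
class FamilyTruth:
    """A generated family: ancestor, member sequences, and the true MSA."""

    spec: FamilySpec
    ancestor: str
    members: dict[str, str]          # member id -> ungapped sequence
    msa: MSA                         # true alignment of the members
    member_rows: dict[str, str]      # member id -> aligned row (match cols only)

    @property
    def family_id(self) -> str:
        return self.spec.family_id

    def member_ancestor_identity(self, member_id: str) -> float:
        """Identity to the ancestor over co-aligned (non-indel) columns."""
        row = self.member_rows[member_id]
        n_aligned = sum(1 for a, b in zip(row, self.ancestor) if a != "-")
        if n_aligned == 0:
            return 0.0
        n_same = sum(1 for a, b in zip(row, self.ancestor) if a != "-" and a == b)
        return n_same / n_aligned

    def mean_member_ancestor_identity(self) -> float:
        return float(np.mean([self.member_ancestor_identity(m)
                              for m in self.members]))


def generate_family(spec: FamilySpec,
                    background: np.ndarray | None = None) -> FamilyTruth:
    """Evolve ``n_members`` sequences from a random ancestor.

    Substitutions are i.i.d. per site with probability ``1 - target_identity``
    and replacements drawn from the background; indel events are Poisson with
    mean ``indel_rate * domain_length`` per member, each a geometric-length
    (mean 2) insertion or deletion placed uniformly.  The true MSA records the
    homologous (ancestor) columns; inserted residues occupy extra gap-padded
    columns.  Identical seeds give identical output.
    """
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background)
    bg = bg / bg.sum()
    rng = np.random.default_rng(spec.seed)
    L = spec.domain_length
    ancestor = random_sequence(L, rng, bg)
    p_sub = 1.0 - spec.target_identity

    members: dict[str, str] = {}
    match_rows: dict[str, list[str]] = {}
    inserts: dict[str, list[str]] = {}
    width = len(str(max(spec.n_members - 1, 1)))
    for m in range(spec.n_members):
        mid = f"{spec.family_id}_m{m:0{width}d}"
        res = list(ancestor)
        sub_mask = rng.random(L) < p_sub
        repl = rng.choice(20, size=int(sub_mask.sum()), p=bg)
        for pos, code in zip(np.flatnonzero(sub_mask), repl):
            res[pos] = AMINO_ACIDS[code]
        ins = [""] * (L + 1)
        n_events = rng.poisson(spec.indel_rate * L)
        for _ in range(n_events):
            length = int(rng.geometric(0.5))  # mean 2
            pos = int(rng.integers(0, L + 1))
            if rng.random() < 0.5:
                ins[pos] += random_sequence(length, rng, bg)
            else:
                for k in range(pos, min(pos + length, L)):
                    res[k] = "-"
        match_rows[mid] = res
        inserts[mid] = ins
        members[mid] = "".join(
            ins[i] + (res[i] if i < L and res[i] != "-" else "")
            for i in range(L + 1)
        )

    ins_width = [max(len(inserts[m][i]) for m in members) for i in range(L + 1)]
    rows = []
    for mid in members:
        parts = []
        for i in range(L + 1):
            parts.append(inserts[mid][i].ljust(ins_width[i], "-"))
            if i < L:
                parts.append(match_rows[mid][i])
        rows.append("".join(parts))
    msa = MSA(ids=list(members), rows=rows, master_index=0)
    member_rows = {mid: "".join(match_rows[mid]) for mid in members}
    return FamilyTruth(spec=spec, ancestor=ancestor, members=members,
                       msa=msa, member_rows=member_rows)


# ---------------------------------------------------------------------------
# Planting domains and sequence features into proteins
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSpec:
    """A sequence feature to plant: ``coiled_coil`` or ``low_complexity``."""

    kind: str
    length: int = 28
    n_instances: int = 0

    def __post_init__(self):
        if self.kind not in ("coiled_coil", "low_complexity"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("feature length must be positive")


@dataclass
class PlantedProtein:
    """A simulated protein with exact truth about its planted content."""

    protein_id: str
    sequence: str
    truth_intervals: list = field(default_factory=list)   # (family_id, start, end)
    planted_features: list = field(default_factory=list)  # (kind, start, end)

    def __post_init__(self):
        L = len(self.sequence)
        spans = [iv[1:] for iv in self.truth_intervals]
        for s, e in spans:
            if not (1 <= s <= e <= L):
                raise ValueError("truth interval out of sequence bounds")
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("truth intervals overlap")


def coiled_coil_feature(length: int, rng: np.random.Generator) -> str:
    """A heptad repeat with hydrophobic residues forced at positions a and d."""
    out = []
    for i in range(length):
        pos = i % 7
        pool = HYDROPHOBIC if pos in (0, 3) else POLAR_HEPTAD
        out.append(pool[int(rng.integers(len(pool)))])
    return "".join(out)


def low_complexity_feature(length: int, rng: np.random.Generator) -> str:
    """A run drawn from at most three residue types."""
    k = int(rng.integers(1, 4))
    types = rng.choice(list(AMINO_ACIDS), size=k, replace=False)
    return "".join(types[int(rng.integers(k))] for _ in range(length))


def _draw_length(dist, rng: np.random.Generator) -> int:
    if callable(dist):
        n = int(dist(rng))
    elif isinstance(dist, int):
        n = dist
    else:
        lo, hi = dist
        if lo < 0 or hi < lo:
            raise ValueError("linker length distribution has negative support")
        n = int(rng.integers(lo, hi + 1))
    if n < 0:
        raise ValueError("linker length distribution has negative support")
    return n


def plant_proteins(families, n_decoys: int = 0,
                   linker_length_distribution=(25, 75),
                   feature_specs=(), seed: int = 0,
                   decoy_length=(150, 250),
                   background: np.ndarray | None = None) -> list[PlantedProtein]:
    """Embed family members in linker context and generate decoy proteins.

    Each family member becomes one protein ``linker + domain + linker`` with
    background-composition linkers; decoys are pure background.  Features from
    ``feature_specs`` are planted into decoy proteins at non-overlapping
    positions (replacing background residues).  Truth intervals delimit the
    planted material exactly, 1-based inclusive.
    """
    fams = []
    for fam in families:
        if isinstance(fam, FamilyTruth):
            fams.append((fam.family_id, list(fam.members.items())))
        else:
            fid, mem = fam
            fams.append((fid, list(mem)))
    if not fams and n_decoys == 0:
        raise ValueError("at least one family or decoy required")
    rng = np.random.default_rng(seed)
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background)
    proteins: list[PlantedProtein] = []
    for fid, members in fams:
        for mid, seq in members:
            left = _draw_length(linker_length_distribution, rng)
            right = _draw_length(linker_length_distribution, rng)
            full = (random_sequence(left, rng, bg) + seq
                    + random_sequence(right, rng, bg))
            proteins.append(PlantedProtein(
                protein_id=mid, sequence=full,
                truth_intervals=[(fid, left + 1, left + len(seq))]))
    decoys: list[PlantedProtein] = []
    for d in range(n_decoys):
        L = _draw_length(decoy_length, rng)
        decoys.append(PlantedProtein(protein_id=f"decoy_{d:04d}",
                                     sequence=random_sequence(L, rng, bg)))
    for fs in feature_specs:
        makers = {"coiled_coil": coiled_coil_feature,
                  "low_complexity": low_complexity_feature}
        for _ in range(fs.n_instances):
            if not decoys:
                raise ValueError("feature planting requires decoy proteins")
            for _attempt in range(200):
                prot = decoys[int(rng.integers(len(decoys)))]
                L = len(prot.sequence)
                if L < fs.length:
                    continue
                start = int(rng.integers(0, L - fs.length + 1))  # 0-based
                span = (start + 1, start + fs.length)
                if any(not (span[1] < s or span[0] > e)
                       for _, s, e in prot.planted_features):
                    continue
                feat = makers[fs.kind](fs.length, rng)
                prot.sequence = (prot.sequence[:start] + feat
                                 + prot.sequence[start + fs.length:])
                prot.planted_features.append((fs.kind, span[0], span[1]))
                break
            else:
                raise ValueError("could not place feature without overlap")
    return proteins + decoys


# ---------------------------------------------------------------------------
# Expression matrices with planted correlated modules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionSpec:
    """Per-tissue expression simulation with latent-factor modules.

    ``module_defs`` is a list of ``(module_id, gene_ids, rho)``: each module's
    genes load on one latent factor per (tissue, sample) so the expected
    pairwise Pearson correlation within the module equals ``rho``.
    Background genes are independent standard normal noise.
    """

    n_tissues: int = 2
    n_samples_per_tissue: int = 200
    module_defs: tuple = ()
    n_background_genes: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_samples_per_tissue < 3:
            raise ValueError("need at least 3 samples per tissue")
        seen: set[str] = set()
        for mid, genes, rho in self.module_defs:
            if not (0.0 < rho < 1.0):
                raise ValueError("module correlation must be in (0, 1)")
            gs = set(genes)
            if gs & seen:
                raise ValueError("module gene sets must be disjoint")
            seen |= gs


def generate_expression(spec: ExpressionSpec):
    """Return ``(matrices, truth)``: tissue -> genes x samples DataFrame.

    ``truth`` maps module id -> gene set (identical across tissues; values
    differ per tissue and seed).
    """
    rng = np.random.default_rng(spec.seed)
    truth = {mid: set(genes) for mid, genes, _ in spec.module_defs}
    bg_genes = [f"BG{i:04d}" for i in range(spec.n_background_genes)]
    all_genes = [g for _, genes, _ in spec.module_defs for g in genes] + bg_genes
    matrices: dict[str, pd.DataFrame] = {}
    n = spec.n_samples_per_tissue
    for t in range(spec.n_tissues):
        tissue = f"tissue{t + 1:02d}"
        data = {}
        for mid, genes, rho in spec.module_defs:
            z = rng.standard_normal(n)
            for g in genes:
                eps = rng.standard_normal(n)
                data[g] = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * eps
        for g in bg_genes:
            data[g] = rng.standard_normal(n)
        cols = [f"{tissue}_s{j:03d}" for j in range(n)]
        matrices[tissue] = pd.DataFrame(
            [data[g] for g in all_genes], index=all_genes, columns=cols)
    return matrices, truth


# ---------------------------------------------------------------------------
# Interaction tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvidenceModel:
    """Sampling model for interaction evidence metadata."""

    p_experimental: float = 0.8
    p_orthology: float = 0.2
    p_predicted: float = 0.2
    pub_rate: float = 2.5

    def sample(self, rng: np.random.Generator):
        types = set()
        if rng.random() < self.p_experimental:
            types.add("experimental")
        if rng.random() < self.p_orthology:
            types.add("orthology")
        if rng.random() < self.p_predicted:
            types.add("predicted")
        if not types:
            types.add("predicted")
        n_pubs = int(rng.poisson(self.pub_rate)) if "experimental" in types else 0
        return frozenset(types), n_pubs


def generate_ppi_table(proteins, true_pairs, evidence_model,
                       contaminant_ids=(), housekeeping_ids=(),
                       seed: int = 0, n_contaminant_records: int = 0,
                       n_housekeeping_records: int = 0):
    """Build an interaction table with evidence metadata and retained truth.

    ``true_pairs`` are (a, b) id pairs among ``proteins``; additional records
    pair a random protein with a partner drawn from the contaminant or
    housekeeping lists.  ``evidence_model`` is an :class:`EvidenceModel` or a
    callable ``rng -> (evidence_types, n_publications)``.  Returns
    ``(records, truth)`` where truth tags each record's origin.
    """
    from .ppi import InteractionRecord  # local import to avoid cycle

    proteins = list(proteins)
    known = set(proteins) | set(contaminant_ids) | set(housekeeping_ids)
    for a, b in true_pairs:
        if a not in known or b not in known:
            raise KeyError(f"pair ({a}, {b}) references unknown protein ids")
    rng = np.random.default_rng(seed)
    sample = (evidence_model.sample if isinstance(evidence_model, EvidenceModel)
              else evidence_model)
    records, origins = [], []
    for a, b in true_pairs:
        ev, n_pubs = sample(rng)
        records.append(InteractionRecord(a, b, ev, n_pubs))
        origins.append("true_pair")
    for n, ids, tag in ((n_contaminant_records, list(contaminant_ids), "contaminant"),
                        (n_housekeeping_records, list(housekeeping_ids), "housekeeping")):
        for _ in range(n):
            a = proteins[int(rng.integers(len(proteins)))]
            b = ids[int(rng.integers(len(ids)))]
            ev, n_pubs = sample(rng)
            records.append(InteractionRecord(a, b, ev, n_pubs))
            origins.append(tag)
    return records, {"origins": origins}


# ---------------------------------------------------------------------------
# GO DAG and annotations
# ---------------------------------------------------------------------------

def generate_go(dag_depth: int, proteins, annotation_rules=None, seed: int = 0,
                branching: int = 2, n_unrelated_terms: int = 8):
    """Generate a rooted GO-like DAG and per-protein annotations.

    The DAG has a single root, the four terms of interest as its children,
    and below each term of interest ``dag_depth - 1`` levels of synthetic
    child terms (branching factor ``branching``); ``dag_depth = 1`` leaves the
    terms of interest childless.  A few cross-links to shallower terms within
    the same subtree make it a DAG rather than a tree; acyclicity is checked
    on construction.

    ``annotation_rules`` maps protein id -> ("direct", term), ("child", term
    of interest: annotate with a random proper descendant), or ("none",).
    Unlisted proteins get one random unrelated term.
    """
    if dag_depth < 1:
        raise ValueError("dag_depth must be >= 1")
    rng = np.random.default_rng(seed)
    root = "GO:0008150"
    parents: dict[str, set[str]] = {root: set()}
    counter = 9000000
    subtree: dict[str, list[str]] = {}
    for toi in DEFAULT_TERMS_OF_INTEREST:
        parents[toi] = {root}
        level = [toi]
        below: list[str] = []
        for _depth in range(dag_depth - 1):
            nxt = []
            for parent in level:
                for _ in range(branching):
                    term = f"GO:{counter:07d}"
                    counter += 1
                    parents[term] = {parent}
                    nxt.append(term)
            # occasional extra is_a parent from a strictly shallower level
            if nxt and level and rng.random() < 0.5:
                extra_child = nxt[int(rng.integers(len(nxt)))]
                extra_parent = level[int(rng.integers(len(level)))]
                parents[extra_child].add(extra_parent)
            below.extend(nxt)
            level = nxt
        subtree[toi] = below
    unrelated = []
    for _ in range(n_unrelated_terms):
        term = f"GO:{counter:07d}"
        counter += 1
        parents[term] = {root}
        unrelated.append(term)
    dag = GODag(parents)

    annots: AnnotationSet = {}
    rules = annotation_rules or {}
    for pid in proteins:
        rule = rules.get(pid, ("background",))
        kind = rule[0]
        if kind == "none":
            annots[pid] = set()
        elif kind == "direct":
            annots[pid] = {rule[1]}
        elif kind == "child":
            toi = rule[1]
            pool = subtree[toi]
            if not pool:
                raise ValueError(f"{toi} has no children at dag_depth=1")
            annots[pid] = {pool[int(rng.integers(len(pool)))]}
        elif kind == "background":
            annots[pid] = {unrelated[int(rng.integers(len(unrelated)))]}
        else:
            raise ValueError(f"unknown annotation rule {rule!r}")
    return dag, annots


# ---------------------------------------------------------------------------
# Simulation manifest output
# ---------------------------------------------------------------------------

def write_proteins_fasta(proteins, path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    recs = [SeqRecord(Seq(p.sequence), id=p.protein_id, description="")
            for p in proteins]
    SeqIO.write(recs, str(path), "fasta")


def write_truth_tables(proteins, outdir) -> None:
    outdir = Path(outdir)
    dom = [(p.protein_id, fid, s, e)
           for p in proteins for fid, s, e in p.truth_intervals]
    pd.DataFrame(dom, columns=["protein_id", "family_id", "start", "end"]).to_csv(
        outdir / "truth_domains.tsv", sep="\t", index=False)
    feat = [(p.protein_id, kind, s, e)
            for p in proteins for kind, s, e in p.planted_features]
    pd.DataFrame(feat, columns=["protein_id", "kind", "start", "end"]).to_csv(
        outdir / "truth_features.tsv", sep="\t", index=False)


def write_manifest(outdir, payload: dict) -> None:
    with open(Path(outdir) / "manifest.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
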