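"""Orchestration of the remote-homology discovery step.

For each query protein: mask coiled-coil/low-complexity regions, build an
iterative MSA for each searchable region against a sequence database, turn it
into a profile HMM, search a family profile library (profile-to-profile),
validate forward hits by a reciprocal search seeded from the hit's family
region back against the query collection, and catalogue the surviving
candidate domains.  Curation (diversity filter, insert removal, problem-region
elimination) can be applied to any candidate's MSA and the search re-run; on
clean alignments the curated pipeline re-detects what the raw one did.

Also houses small descriptive outputs: percent-identity (PID) distance trees
and pairwise global-alignment identity.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

from .hmm import (ProfileHMM, SearchHit, background_decoy_sampler,
                  calibrate_evd, hmm_from_msa, hmm_hmm_score, search)
from .masking import mask_sequence
from .msa import (MSA, drop_problem_regions, msa_diff_filter,
                  pairwise_identity_aligned, remove_inserts)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds of the discovery pipeline (all tunable, defaults documented).

    ``e_include``: E-value cutoff for adding sequences to the iterative MSA.
    ``e_max``: significance cutoff for forward and reciprocal searches.
    ``min_coverage``: fraction of the forward query region a reciprocal hit
    must cover for validation.
    """

    e_include: float = 0.01
    e_max: float = 0.01
    n_iter: int = 3
    alpha: float = 1.0
    n_calib_decoys: int = 200
    n_decoy_profiles: int = 100
    min_coverage: float = 0.5
    min_region_length: int = 30
    mask_queries: bool = True
    diff_n_keep: int = 30
    min_col_coverage: float = 0.5
    min_seq_residues: int = 10


@dataclass
class CandidateDomain:
    """A protein region assigned to a domain family, with validation status."""

    protein_id: str
    region: tuple          # (start, end) 1-based inclusive on the protein
    family_id: str
    forward_hit: SearchHit
    reciprocal_hit: SearchHit | None = None
    status: str = "forward_only"   # forward_only | validated | rejected
    provenance: str = ""
    reason: str = ""

    def __post_init__(self):
        if self.status not in ("forward_only", "validated", "rejected"):
            raise ValueError(f"bad status {self.status!r}")


@dataclass
class FamilyEntry:
    """A library family: curated MSA plus the profile built from it."""

    family_id: str
    msa: MSA
    hmm: ProfileHMM


def build_family_library(family_msas: dict, alpha: float = 1.0) -> list[FamilyEntry]:
    entries = []
    for fid in sorted(family_msas):
        msa = family_msas[fid]
        entries.append(FamilyEntry(fid, msa, hmm_from_msa(msa, alpha=alpha,
                                                          name=fid)))
    return entries


# ---------------------------------------------------------------------------
# Iterative MSA building
# ---------------------------------------------------------------------------

def iterative_msa_build(query_id: str, query_seq: str, sequence_db,
                        n_iter: int = 3, e_include: float = 0.01,
                        alpha: float = 1.0, seed: int = 0,
                        n_calib_decoys: int = 200,
                        calib_cache: dict | None = None) -> MSA:
    """Iteratively enrich a query MSA from a sequence database.

    Iteration 0 scores the database with a single-sequence profile of the
    query; each iteration includes targets with E <= ``e_include``, realigns
    them to the query master via the Viterbi trace (master-slave: inserted
    target residues are dropped), rebuilds the profile and repeats, stopping
    at ``n_iter`` iterations or at a fixpoint.  Rows are only ever added.
    """
    db = [(tid, s) for tid, s in sequence_db if tid != query_id]
    msa = MSA(ids=[query_id], rows=[query_seq], master_index=0)
    if not db or e_include <= 0:
        return msa
    included: set[str] = set()
    sampler = background_decoy_sampler([len(s) for _, s in db])
    rng = np.random.default_rng(seed)
    for it in range(n_iter):
        hmm = hmm_from_msa(msa, alpha=alpha, name=query_id)
        # a single-sequence profile's decoy score distribution depends only
        # on its length under the uniform background, so its calibration can
        # be shared across queries
        key = ("single", hmm.n_match) if msa.n_rows == 1 else None
        if key is not None and calib_cache is not None and key in calib_cache:
            evd = calib_cache[key].with_n_db(len(db))
        else:
            evd = calibrate_evd(hmm, sampler, n_decoys=n_calib_decoys,
                                seed=int(rng.integers(2 ** 31)), n_db=len(db))
            if key is not None and calib_cache is not None:
                calib_cache[key] = evd
        hits = search(hmm, db, evd, e_max=e_include)
        new = [h for h in hits if h.target_id not in included]
        if not new:
            break
        seqs = dict(db)
        width = len(query_seq)
        for h in new:
            included.add(h.target_id)
            row = ["-"] * width
            tseq = seqs[h.target_id]
            for tpos, mstate in h.trace:
                col = int(hmm.master_positions[mstate - 1])
                if col >= 0:
                    row[col] = tseq[tpos - 1]
            msa = MSA(ids=msa.ids + [h.target_id], rows=msa.rows + ["".join(row)],
                      master_index=0)
    if msa.n_rows == 1:
        logger.info("iterative build found no homologs for %s", query_id)
    return msa


# ---------------------------------------------------------------------------
# Forward search and reciprocal validation
# ---------------------------------------------------------------------------

@dataclass
class QueryProfile:
    """A query protein's searchable region with its iterative MSA and HMM."""

    protein_id: str
    sequence: str          # full protein sequence
    region: tuple          # searchable region (start, end), 1-based inclusive
    msa: MSA
    hmm: ProfileHMM
    provenance: str = ""

    def protein_interval(self, q_start: int, q_end: int) -> tuple:
        """Map a hit's match-state interval to protein coordinates.

        Master residue indices are translated through the MSA's column
        provenance map, so the mapping stays correct after curation has
        removed columns.
        """
        mp = self.hmm.master_positions
        res_cols = [i for i, ch in enumerate(self.msa.master)
                    if ch not in "-."]
        cmap = self.msa.col_map
        cols = []
        for k in range(q_start, q_end + 1):
            r = int(mp[k - 1])
            if r >= 0:
                col = res_cols[r]
                cols.append(cmap[col] if cmap is not None else col)
        if not cols:
            return (self.region[0], self.region[0])
        return (self.region[0] + min(cols), self.region[0] + max(cols))


def build_query_profiles(protein_id: str, sequence: str, sequence_db,
                         config: PipelineConfig, seed: int = 0,
                         provenance: str = "",
                         calib_cache: dict | None = None) -> list[QueryProfile]:
    """Mask a query and build one iterative profile per searchable region."""
    if config.mask_queries:
        _, regions = mask_sequence(seq=sequence)
        regions = [(s, e) for s, e in regions
                   if e - s + 1 >= config.min_region_length]
    else:
        regions = [(1, len(sequence))]
    out = []
    for i, (s, e) in enumerate(regions):
        sub = sequence[s - 1:e]
        msa = iterative_msa_build(protein_id, sub, sequence_db,
                                  n_iter=config.n_iter,
                                  e_include=config.e_include,
                                  alpha=config.alpha,
                                  seed=seed + 7919 * i,
                                  n_calib_decoys=config.n_calib_decoys,
                                  calib_cache=calib_cache)
        hmm = hmm_from_msa(msa, alpha=config.alpha, name=protein_id)
        out.append(QueryProfile(protein_id=protein_id, sequence=sequence,
                                region=(s, e), msa=msa, hmm=hmm,
                                provenance=provenance))
    if not out:
        logger.warning("query %s fully masked; skipped", protein_id)
    return out


def make_decoy_profiles(n: int, seed: int, domain_length: int = 100,
                        n_members: int = 30, identity: float = 0.4) -> list:
    """Decoy family profiles for profile-profile E-value calibration.

    Synthetic families with the same shape as the library (member count,
    divergence, length) but unrelated random ancestors.
    """
    from .synthetic import FamilySpec, generate_family
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        fam = generate_family(FamilySpec(
            family_id=f"decoyfam{i:03d}", domain_length=domain_length,
            n_members=n_members, target_identity=identity, indel_rate=0.0,
            seed=int(rng.integers(2 ** 31))))
        out.append(hmm_from_msa(fam.msa, name=fam.family_id))
    return out


def profile_decoy_sampler(decoy_profiles):
    def sampler(rng: np.random.Generator, n: int):
        idx = rng.choice(len(decoy_profiles), size=n,
                         replace=n > len(decoy_profiles))
        return [decoy_profiles[i] for i in idx]
    return sampler


def _hhscore(q, t):
    return hmm_hmm_score(q, t)


def forward_search_all(query_profiles, library, decoy_profiles,
                       e_max: float = 0.01, seed: int = 0,
                       calib_cache: dict | None = None) -> list:
    """Profile-profile search of every query against the family library.

    Each query profile gets its own Gumbel calibration against the decoy
    profile set; hits with E <= ``e_max`` are returned as ``(query_profile,
    SearchHit)`` pairs, hit intervals in query-HMM columns and family-HMM
    columns.  Single-sequence query profiles of equal length share a
    calibration (their decoy score distribution is identical under the
    uniform background).
    """
    sampler = profile_decoy_sampler(decoy_profiles)
    rng = np.random.default_rng(seed)
    targets = [(f.family_id, f.hmm) for f in library]
    out = []
    for qp in query_profiles:
        key = (("hh_single", qp.hmm.n_match)
               if qp.msa.n_rows == 1 else None)
        if key is not None and calib_cache is not None and key in calib_cache:
            evd = calib_cache[key].with_n_db(len(library))
        else:
            evd = calibrate_evd(qp.hmm, sampler, n_decoys=len(decoy_profiles),
                                seed=int(rng.integers(2 ** 31)),
                                n_db=len(library), score_fn=_hhscore)
            if key is not None and calib_cache is not None:
                calib_cache[key] = evd
        for h in search(qp.hmm, targets, evd, e_max=e_max):
            out.append((qp, h))
    return out


def _slice_family_msa(entry: FamilyEntry, t_start: int, t_end: int) -> MSA:
    """Columns of the family MSA spanned by a hit's family-HMM interval."""
    mc = entry.hmm._cache.get("match_cols")
    if mc is None:
        raise RuntimeError("family HMM lacks match-column map")
    cols = mc[t_start - 1:t_end]
    rows = ["".join(r[c] for c in cols) for r in entry.msa.rows]
    return MSA(ids=list(entry.msa.ids), rows=rows,
               master_index=entry.msa.master_index)


def reciprocal_validate(qp: QueryProfile, hit: SearchHit, entry: FamilyEntry,
                        query_collection, forward_best_family: dict,
                        e_max: float = 0.01, min_coverage: float = 0.5,
                        seed: int = 0, alpha: float = 1.0,
                        n_calib_decoys: int = 200) -> CandidateDomain:
    """Validate a forward hit by searching back from the family region.

    An HMM seeded from the family MSA region of the hit is searched against
    the full query collection (sequences).  The candidate is validated iff a
    reciprocal hit with E <= ``e_max`` covers at least ``min_coverage`` of
    the original query region on the original query protein AND the query's
    best forward family assignment equals this hit's family.
    """
    region = qp.protein_interval(hit.q_start, hit.q_end)
    cand = CandidateDomain(protein_id=qp.protein_id, region=region,
                           family_id=hit.target_id, forward_hit=hit,
                           provenance=qp.provenance)
    try:
        sub = _slice_family_msa(entry, hit.t_start, hit.t_end)
        rhmm = hmm_from_msa(sub, alpha=alpha, name=f"{entry.family_id}_recip")
    except (ValueError, RuntimeError) as exc:
        cand.status = "rejected"
        cand.reason = f"reciprocal model failed: {exc}"
        return cand
    collection = list(query_collection)
    sampler = background_decoy_sampler([len(s) for _, s in collection])
    evd = calibrate_evd(rhmm, sampler, n_decoys=n_calib_decoys, seed=seed,
                        n_db=len(collection))
    rhits = search(rhmm, collection, evd, e_max=e_max)
    rs, re = region
    for rh in rhits:
        if rh.target_id != qp.protein_id:
            continue
        overlap = min(re, rh.t_end) - max(rs, rh.t_start) + 1
        if overlap / (re - rs + 1) >= min_coverage:
            cand.reciprocal_hit = rh
            break
    consistent = forward_best_family.get(qp.protein_id) == hit.target_id
    if cand.reciprocal_hit is not None and consistent:
        cand.status = "validated"
    else:
        cand.status = "forward_only"
    return cand


def curate_and_retry(qp: QueryProfile, cand: CandidateDomain, library,
                     decoy_profiles, query_collection,
                     config: PipelineConfig, seed: int = 0) -> CandidateDomain:
    """Re-run forward + reciprocal with a curated query MSA.

    Curation: diversity filter to ``diff_n_keep`` rows, removal of insert
    columns relative to the master, then elimination of fragment rows and
    sparsely covered columns.  Single-row MSAs pass through unchanged.  If
    curation empties the alignment the candidate is rejected with a reason.
    """
    msa = qp.msa
    if msa.n_rows == 1:
        curated = msa
    else:
        try:
            curated = msa_diff_filter(msa, n_keep=config.diff_n_keep)
            curated = remove_inserts(curated)
            curated = drop_problem_regions(curated,
                                           min_col_coverage=config.min_col_coverage,
                                           min_seq_residues=config.min_seq_residues)
        except ValueError as exc:
            return CandidateDomain(protein_id=cand.protein_id,
                                   region=cand.region,
                                   family_id=cand.family_id,
                                   forward_hit=cand.forward_hit,
                                   status="rejected",
                                   provenance=cand.provenance,
                                   reason=str(exc))
    qp2 = QueryProfile(protein_id=qp.protein_id, sequence=qp.sequence,
                       region=qp.region, msa=curated,
                       hmm=hmm_from_msa(curated, alpha=config.alpha,
                                        name=qp.protein_id),
                       provenance=qp.provenance)
    hits = forward_search_all([qp2], library, decoy_profiles,
                              e_max=config.e_max, seed=seed)
    best: dict[str, SearchHit] = {}
    for _, h in hits:
        if h.query_id not in best or h.evalue < best[h.query_id].evalue:
            best[h.query_id] = h
    fbest = {pid: h.target_id for pid, h in best.items()}
    own = [h for _, h in hits if h.target_id == cand.family_id]
    if not own:
        return CandidateDomain(protein_id=cand.protein_id, region=cand.region,
                               family_id=cand.family_id,
                               forward_hit=cand.forward_hit,
                               status="forward_only",
                               provenance=cand.provenance,
                               reason="curated profile lost the forward hit")
    entry = next(e for e in library if e.family_id == cand.family_id)
    return reciprocal_validate(qp2, own[0], entry, query_collection, fbest,
                               e_max=config.e_max,
                               min_coverage=config.min_coverage,
                               seed=seed, alpha=config.alpha,
                               n_calib_decoys=config.n_calib_decoys)


# ---------------------------------------------------------------------------
# End-to-end discovery
# ---------------------------------------------------------------------------

def run_discovery(queries, library, sequence_db, config: PipelineConfig,
                  seed: int = 0, provenance: dict | None = None):
    """Full step-2 pipeline on a query set.

    ``queries``: list of (protein_id, sequence); ``library``: FamilyEntry
    list; ``sequence_db``: (id, sequence) pool for iterative MSA building.
    Returns ``(candidates, report)``.
    """
    rng = np.random.default_rng(seed)
    provenance = provenance or {}
    lib_shape = library[0].hmm.n_match if library else 100
    decoy_profiles = make_decoy_profiles(
        config.n_decoy_profiles, seed=int(rng.integers(2 ** 31)),
        domain_length=lib_shape,
        n_members=min(30, max(2, library[0].msa.n_rows if library else 30)))
    calib_cache: dict = {}
    qprofiles = []
    for pid, seq in queries:
        qprofiles.extend(build_query_profiles(
            pid, seq, sequence_db, config, seed=int(rng.integers(2 ** 31)),
            provenance=provenance.get(pid, ""), calib_cache=calib_cache))
    fhits = forward_search_all(qprofiles, library, decoy_profiles,
                               e_max=config.e_max,
                               seed=int(rng.integers(2 ** 31)),
                               calib_cache=calib_cache)
    best: dict[str, SearchHit] = {}
    for qp, h in fhits:
        if h.query_id not in best or h.evalue < best[h.query_id].evalue:
            best[h.query_id] = h
    fbest = {pid: h.target_id for pid, h in best.items()}
    entries = {e.family_id: e for e in library}
    candidates = []
    seen: set[tuple] = set()
    for qp, h in fhits:
        if best.get(qp.protein_id) is not h:
            continue  # validate the best forward hit per query
        key = (qp.protein_id, qp.region)
        if key in seen:
            continue
        seen.add(key)
        cand = reciprocal_validate(qp, h, entries[h.target_id], queries,
                                   fbest, e_max=config.e_max,
                                   min_coverage=config.min_coverage,
                                   seed=int(rng.integers(2 ** 31)),
                                   alpha=config.alpha,
                                   n_calib_decoys=config.n_calib_decoys)
        candidates.append((cand, qp))
    report = catalog_report([c for c, _ in candidates],
                            funnel={"queries": len(queries),
                                    "query_profiles": len(qprofiles),
                                    "forward_hits": len(fhits),
                                    "candidates": len(candidates)})
    return candidates, report


# ---------------------------------------------------------------------------
# Descriptive outputs
# ---------------------------------------------------------------------------

def pid_distance_tree(msa: MSA) -> str:
    """Average-linkage tree from percent-identity distances, as newick.

    d(i, j) = 1 - identity over columns where both rows carry a residue;
    pairs with no co-aligned columns get d = 1 (logged).  The dendrogram is
    ultrametric by construction (branch length to a child = half the height
    difference).
    """
    n = msa.n_rows
    if n < 3:
        raise ValueError("PID tree needs at least 3 rows")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = msa.rows[i], msa.rows[j]
            both = sum(1 for x, y in zip(a, b)
                       if x not in "-." and y not in "-.")
            if both == 0:
                logger.warning("rows %s and %s share no columns; distance 1",
                               msa.ids[i], msa.ids[j])
                d = 1.0
            else:
                d = 1.0 - pairwise_identity_aligned(a, b)
            D[i, j] = D[j, i] = d
    Z = average(squareform(D, checks=False))
    heights = {i: 0.0 for i in range(n)}
    names = {i: msa.ids[i] for i in range(n)}
    for step, (a, b, h, _cnt) in enumerate(Z):
        a, b = int(a), int(b)
        node = n + step
        la = h / 2.0 - heights[a]
        lb = h / 2.0 - heights[b]
        names[node] = f"({names[a]}:{max(la, 0.0):.10f},{names[b]}:{max(lb, 0.0):.10f})"
        heights[node] = h / 2.0
        del names[a], names[b]
    (root,) = names.values()
    return root + ";"


_ALIGNER = None


def _aligner() -> Align.PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        a = Align.PairwiseAligner()
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -10.0
        a.extend_gap_score = -0.5
        a.mode = "global"
        _ALIGNER = a
    return _ALIGNER


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity from one optimal global alignment.

    BLOSUM62 with affine gaps (open 10, extend 0.5).  Identity is
    100 x identical columns / alignment columns, excluding terminal-gap
    overhangs (and columns gapped in both rows, which a pairwise alignment
    does not produce).  Symmetric in its arguments.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aln = _aligner().align(seq_a.upper(), seq_b.upper())[0]
    a_row = aln[0]
    b_row = aln[1]
    # trim terminal-gap overhangs
    start = 0
    end = len(a_row)
    while a_row[start] == "-" or b_row[start] == "-":
        start += 1
    while a_row[end - 1] == "-" or b_row[end - 1] == "-":
        end -= 1
    cols = 0
    same = 0
    for x, y in zip(a_row[start:end], b_row[start:end]):
        if x == "-" and y == "-":
            continue
        cols += 1
        if x == y and x != "-":
            same += 1
    if cols == 0:
        return 0.0
    return 100.0 * same / cols


def catalog_report(candidates, funnel: dict | None = None) -> dict:
    """Deterministic structured report over candidate domains."""
    by_status: dict[str, int] = {}
    by_family: dict[str, int] = {}
    by_provenance: dict[str, int] = {}
    records = []
    for c in sorted(candidates, key=lambda c: (c.protein_id, c.region)):
        by_status[c.status] = by_status.get(c.status, 0) + 1
        by_family[c.family_id] = by_family.get(c.family_id, 0) + 1
        key = c.provenance or "unknown"
        by_provenance[key] = by_provenance.get(key, 0) + 1
        records.append({
            "protein_id": c.protein_id,
            "region": list(c.region),
            "family_id": c.family_id,
            "status": c.status,
            "forward_bits": round(c.forward_hit.score, 4),
            "forward_evalue": c.forward_hit.evalue,
            "reciprocal_evalue": (c.reciprocal_hit.evalue
                                  if c.reciprocal_hit else None),
            "provenance": c.provenance,
            "reason": c.reason,
        })
    return {
        "counts_by_status": dict(sorted(by_status.items())),
        "counts_by_family": dict(sorted(by_family.items())),
        "counts_by_provenance": dict(sorted(by_provenance.items())),
        "attrition": funnel or {},
        "candidates": records,
    }


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
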