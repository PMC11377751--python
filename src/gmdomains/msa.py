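"""Multiple sequence alignments: container, curation operations, Stockholm/A3M I/O.

The curation operations mirror the standard HH-suite style MSA hygiene applied
before profile construction: diversity filtering to a bounded number of
maximally dissimilar rows, removal of insert columns relative to a designated
master (query) row, and elimination of problem rows/columns (fragments and
sparsely covered columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP_CHARS = "-."


@dataclass
class MSA:
    """A gapped alignment with a designated master (query) row.

    Rows are plain strings over the residue alphabet plus ``-``; all rows have
    equal length.  ``master_index`` designates the query sequence that profile
    construction and master-slave operations are anchored on.  ``col_map``,
    when set, records for every current column its index in the alignment the
    curation chain started from, so coordinates survive column removal.
    """

    ids: list[str]
    rows: list[str]
    master_index: int = 0
    labels: dict[str, str] = field(default_factory=dict)
    col_map: list | None = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("MSA must have at least one row")
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise ValueError("MSA rows must have equal length")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows length mismatch")
        if not (0 <= self.master_index < len(self.rows)):
            raise ValueError("master_index out of range")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @property
    def master(self) -> str:
        return self.rows[self.master_index]

    @property
    def master_id(self) -> str:
        return self.ids[self.master_index]

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "").replace(".", "")

    def to_array(self) -> np.ndarray:
        """Character matrix (n_rows, n_cols) of single-byte strings."""
        return np.array([list(r) for r in self.rows], dtype="U1")


def pairwise_identity_aligned(row_a: str, row_b: str) -> float:
    """Fractional identity over columns where both rows carry a residue.

    Pairs with zero co-aligned columns get identity 0 (maximal distance).
    """
    a = np.frombuffer(row_a.encode(), dtype=np.uint8)
    b = np.frombuffer(row_b.encode(), dtype=np.uint8)
    gap = (a == ord("-")) | (a == ord(".")) | (b == ord("-")) | (b == ord("."))
    both = ~gap
    n = int(both.sum())
    if n == 0:
        return 0.0
    return float((a[both] == b[both]).sum()) / n


def msa_diff_filter(msa: MSA, n_keep: int = 30) -> MSA:
    """Reduce an MSA to a diverse subset of at most ``n_keep`` rows.

    Greedy maximin selection: the master is always kept; each step adds the
    row whose maximum pairwise identity to the already-kept set is lowest
    (i.e. the most dissimilar remaining row), breaking ties by row order.
    This emulates the ``hhfilter -diff`` style reduction that preserves the
    sequences most dissimilar to the query.
    """
    if msa.n_rows <= n_keep:
        return msa
    n = msa.n_rows
    ident = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident[i, j] = ident[j, i] = pairwise_identity_aligned(msa.rows[i], msa.rows[j])
    kept = [msa.master_index]
    remaining = [i for i in range(n) if i != msa.master_index]
    while remaining and len(kept) < n_keep:
        # max identity of each remaining row to the kept set
        max_id = [max(ident[r, k] for k in kept) for r in remaining]
        best = int(np.argmin(max_id))  # first minimum -> tie by row order
        kept.append(remaining.pop(best))
    kept_sorted = sorted(kept)
    return MSA(
        ids=[msa.ids[i] for i in kept_sorted],
        rows=[msa.rows[i] for i in kept_sorted],
        master_index=kept_sorted.index(msa.master_index),
        labels=msa.labels,
        col_map=msa.col_map,
    )


def remove_inserts(msa: MSA) -> MSA:
    """Delete every column where the master row has a gap (master-slave form).

    The resulting master row is gap-free; the row count is unchanged.  This is
    the ``remove all inserts`` refinement producing an alignment whose columns
    correspond one-to-one to master residues.
    """
    keep = [i for i, c in enumerate(msa.master) if c not in GAP_CHARS]
    rows = ["".join(r[i] for i in keep) for r in msa.rows]
    old_map = msa.col_map if msa.col_map is not None else list(range(msa.n_cols))
    return MSA(ids=list(msa.ids), rows=rows, master_index=msa.master_index,
               labels=msa.labels, col_map=[old_map[i] for i in keep])


def drop_problem_regions(msa: MSA, min_col_coverage: float = 0.5,
                         min_seq_residues: int = 10) -> MSA:
    """Remove fragment rows, then sparsely covered columns.

    Rows with fewer than ``min_seq_residues`` residues are dropped first;
    columns whose residue coverage (fraction of surviving rows with a residue)
    falls below ``min_col_coverage`` are dropped second.  The master must
    survive and at least two rows must remain, otherwise curation has emptied
    the alignment and a ``ValueError`` is raised.
    """
    keep_rows = [i for i in range(msa.n_rows)
                 if len(msa.ungapped(i)) >= min_seq_residues]
    if msa.master_index not in keep_rows or len(keep_rows) < 2:
        raise ValueError("curation emptied alignment")
    rows = [msa.rows[i] for i in keep_rows]
    arr = np.array([list(r) for r in rows], dtype="U1")
    residue = ~np.isin(arr, list(GAP_CHARS))
    coverage = residue.mean(axis=0)
    keep_cols = np.flatnonzero(coverage >= min_col_coverage)
    if keep_cols.size == 0:
        raise ValueError("curation emptied alignment")
    new_rows = ["".join(arr[r, keep_cols]) for r in range(len(rows))]
    old_map = msa.col_map if msa.col_map is not None else list(range(msa.n_cols))
    return MSA(
        ids=[msa.ids[i] for i in keep_rows],
        rows=new_rows,
        master_index=keep_rows.index(msa.master_index),
        labels=msa.labels,
        col_map=[old_map[int(i)] for i in keep_cols],
    )


# ---------------------------------------------------------------------------
# Stockholm I/O (via Biopython) and the A3M dialect (hand-rolled: lowercase
# residues are inserts relative to the master and carry no column).
# ---------------------------------------------------------------------------

def to_biopython(msa: MSA) -> MultipleSeqAlignment:
    return MultipleSeqAlignment(
        [SeqRecord(Seq(r), id=i, description="") for i, r in zip(msa.ids, msa.rows)]
    )


def write_stockholm(msa: MSA, path) -> None:
    AlignIO.write(to_biopython(msa), str(path), "stockholm")


def read_stockholm(path, master_id: str | None = None) -> MSA:
    aln = AlignIO.read(str(path), "stockholm")
    ids = [rec.id for rec in aln]
    rows = [str(rec.seq).upper().replace(".", "-") for rec in aln]
    master_index = ids.index(master_id) if master_id is not None else 0
    return MSA(ids=ids, rows=rows, master_index=master_index)


def write_a3m(msa: MSA, handle) -> None:
    """Write A3M: insert columns (master gap) become lowercase, no gap padding."""
    close = False
    if isinstance(handle, (str, bytes)) or hasattr(handle, "__fspath__"):
        handle = open(handle, "w")
        close = True
    try:
        master = msa.master
        is_insert = [c in GAP_CHARS for c in master]
        for sid, row in zip(msa.ids, msa.rows):
            out = []
            for c, ins in zip(row, is_insert):
                if ins:
                    if c not in GAP_CHARS:
                        out.append(c.lower())
                else:
                    out.append(c.upper() if c not in GAP_CHARS else "-")
            handle.write(f">{sid}\n{''.join(out)}\n")
    finally:
        if close:
            handle.close()


def read_a3m(handle, master_index: int = 0) -> MSA:
    """Read A3M, re-inflating lowercase inserts into gap-padded columns.

    Inserts between the same pair of match columns are left-justified into a
    shared block of columns; ``remove_inserts`` on the result drops exactly
    the lowercase material, so A3M round-trips through the master-slave form.
    """
    if isinstance(handle, (str, bytes)) or hasattr(handle, "__fspath__"):
        with open(handle) as fh:
            return read_a3m(fh, master_index)
    ids, raws = [], []
    cur = None
    for line in handle:
        line = line.rstrip("\n")
        if line.startswith(">"):
            ids.append(line[1:].split()[0])
            raws.append([])
        elif line:
            raws[-1].append(line)
    seqs = ["".join(parts) for parts in raws]
    if not seqs:
        raise ValueError("empty A3M")
    # split each sequence into match symbols and insert runs after each match col
    n_match = sum(1 for c in seqs[0] if not c.islower())
    parsed = []
    for s in seqs:
        match_syms = []
        inserts = [[] for _ in range(n_match + 1)]  # inserts[i] precedes match col i
        for c in s:
            if c.islower():
                inserts[len(match_syms)].append(c.upper())
            else:
                match_syms.append(c)
        if len(match_syms) != n_match:
            raise ValueError("A3M rows disagree on match-column count")
        parsed.append((match_syms, ["".join(x) for x in inserts]))
    ins_width = [max(len(p[1][i]) for p in parsed) for i in range(n_match + 1)]
    rows = []
    for match_syms, inserts in parsed:
        out = []
        for i in range(n_match + 1):
            out.append(inserts[i].ljust(ins_width[i], "-"))
            if i < n_match:
                out.append(match_syms[i])
        rows.append("".join(out))
    return MSA(ids=ids, rows=rows, master_index=master_index)
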