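"""Profile hidden Markov models: construction, scoring, and E-value machinery.

The model is a local-alignment profile HMM: M match states with
position-specific emissions, insert states emitting background, and delete
states, with entry into any match state at any target position (probability
``1/(M*L)``) and a per-state exit probability.  Scores are log2 odds against
the i.i.d. background model.  This is a deliberately simple local
architecture with testable closed forms — a documented deviation from the
Plan7 flanking-state design.

Profile-to-profile comparison aligns match columns of two models with the
co-emission log-odds column score ``S(i,j) = log2 sum_a e_q[i][a] e_t[j][a]
/ f[a]`` under affine gap costs.

Significance is calibrated empirically: optimal-alignment (Viterbi) scores of
background decoys are fitted with a Gumbel distribution by maximum
likelihood, and ``E(s) = n_db * P(S >= s)`` under that fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gumbel_r

from . import _kernels
from .alphabet import AMINO_ACIDS, encode
from .msa import MSA, GAP_CHARS

LN2 = float(np.log(2.0))

DEFAULT_ALPHA = 1.0          # background-proportional pseudocount weight
DEFAULT_EXIT_PROB = 0.02     # exit probability from internal match states
DEFAULT_TRANS_PSEUDO = 0.02  # transition pseudocount (weight units; weights sum 1)
DEFAULT_GAP_OPEN = 3.0       # bits, profile-profile alignment
DEFAULT_GAP_EXTEND = 0.3     # bits


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class ProfileHMM:
    """A local-alignment profile HMM over a residue alphabet.

    ``match_emit[k]`` is the emission distribution of match state k (1-based
    in reports, 0-based here); insert states emit ``background``.  Transition
    arrays are indexed by source position k (valid for k < n_match - 1):
    ``t_mm/t_mi/t_md`` from match k, ``t_im/t_ii`` from insert k,
    ``t_dm/t_dd`` from delete k; ``t_me[k]`` is the exit probability of match
    state k (1.0 for the final state).  ``master_positions[k]`` maps match
    state k to a 0-based residue index of the source MSA's master row (or -1).
    """

    name: str
    match_emit: np.ndarray
    background: np.ndarray
    t_mm: np.ndarray
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    t_me: np.ndarray
    alphabet: str = AMINO_ACIDS
    master_positions: np.ndarray | None = None
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_match(self) -> int:
        return self.match_emit.shape[0]

    @property
    def n_letters(self) -> int:
        return len(self.alphabet)

    def validate(self, tol: float = 1e-9) -> None:
        M = self.n_match
        if M < 1:
            raise ValueError("profile HMM needs at least one match state")
        if not np.allclose(self.match_emit.sum(axis=1), 1.0, atol=tol):
            raise ValueError("match emission rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=tol):
            raise ValueError("background must sum to 1")
        if M >= 2:
            # transitions into the final column cannot enter dead-end states
            out_m = self.t_mm[:M - 1] + self.t_mi[:M - 1] + self.t_md[:M - 1] \
                + self.t_me[:M - 1]
            if not np.allclose(out_m, 1.0, atol=tol):
                raise ValueError("match-state outgoing probabilities must sum to 1")
            out_i = self.t_im[:M - 1] + self.t_ii[:M - 1]
            if not np.allclose(out_i, 1.0, atol=tol):
                raise ValueError("insert-state outgoing probabilities must sum to 1")
            out_d = self.t_dm[:M - 1] + self.t_dd[:M - 1]
            if not np.allclose(out_d, 1.0, atol=tol):
                raise ValueError("delete-state outgoing probabilities must sum to 1")
        if not np.isclose(self.t_me[M - 1], 1.0, atol=tol):
            raise ValueError("final match state must exit with probability 1")

    # -- log-space views used by the kernels --------------------------------

    def _log(self, x: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            out = np.log(x)
        return np.where(np.isfinite(out), out, _kernels.NEG_INF)

    def kernel_args(self):
        if "kargs" not in self._cache:
            K = self.n_letters
            lo = np.full((self.n_match, K + 1), 0.0)
            with np.errstate(divide="ignore"):
                lo[:, :K] = np.log(self.match_emit) - np.log(self.background)
            lo[:, :K] = np.where(np.isfinite(lo[:, :K]), lo[:, :K],
                                 _kernels.NEG_INF)
            self._cache["kargs"] = (
                lo,
                self._log(self.t_mm), self._log(self.t_mi), self._log(self.t_md),
                self._log(self.t_im), self._log(self.t_ii),
                self._log(self.t_dm), self._log(self.t_dd),
                self._log(self.t_me),
            )
        return self._cache["kargs"]

    def encode(self, seq: str) -> np.ndarray:
        if self.alphabet == AMINO_ACIDS:
            return encode(seq)
        lut = {c: i for i, c in enumerate(self.alphabet)}
        return np.array([lut.get(c, self.n_letters) for c in seq], dtype=np.int64)


def uniform_background(n_letters: int = 20) -> np.ndarray:
    return np.full(n_letters, 1.0 / n_letters)


# ---------------------------------------------------------------------------
# Construction from an MSA
# ---------------------------------------------------------------------------

def henikoff_weights(char_matrix: np.ndarray, alphabet: str) -> np.ndarray:
    """Henikoff & Henikoff position-based sequence weights, normalised to sum 1.

    Per column with r distinct residues, a sequence carrying a residue seen s
    times contributes 1/(r*s); gaps contribute nothing.  Row order does not
    affect the result.
    """
    n_rows, n_cols = char_matrix.shape
    # map characters to small integers; gaps -> -1
    codes = np.full((n_rows, n_cols), -1, dtype=np.int64)
    symbols = sorted({c for c in char_matrix.ravel() if c not in GAP_CHARS})
    for i, sym in enumerate(symbols):
        codes[char_matrix == sym] = i
    n_sym = max(len(symbols), 1)
    w = np.zeros(n_rows)
    flat_cols = np.broadcast_to(np.arange(n_cols), (n_rows, n_cols))
    valid = codes >= 0
    counts = np.zeros((n_cols, n_sym))
    np.add.at(counts, (flat_cols[valid], codes[valid]), 1.0)
    r_per_col = (counts > 0).sum(axis=1)
    with np.errstate(divide="ignore"):
        contrib = 1.0 / (r_per_col[:, None] * counts)
    contrib[counts == 0] = 0.0
    w = np.where(valid, contrib[flat_cols, np.where(valid, codes, 0)], 0.0).sum(axis=1)
    total = w.sum()
    if total == 0:
        return np.full(n_rows, 1.0 / n_rows)
    return w / total


def hmm_from_msa(msa: MSA, alpha: float = DEFAULT_ALPHA,
                 match_gap_fraction: float = 0.5,
                 background: np.ndarray | None = None,
                 exit_prob: float = DEFAULT_EXIT_PROB,
                 trans_pseudo: float = DEFAULT_TRANS_PSEUDO,
                 alphabet: str = AMINO_ACIDS,
                 name: str | None = None) -> ProfileHMM:
    """Estimate a profile HMM from an alignment.

    Columns with gap fraction strictly below ``match_gap_fraction`` become
    match states.  Emissions use Henikoff position-based sequence weights
    with background-proportional pseudocounts ``alpha * f[a]``; transitions
    come from weighted state-path counts with additive smoothing
    (``trans_pseudo`` per category).  Because sequence weights are
    normalised to sum to one, the smoothing weight is kept small so that a
    single-sequence model still favours match-match continuation.  Residues
    outside the alphabet contribute their weight to the background part of a
    column.
    """
    K = len(alphabet)
    bg = (np.full(K, 1.0 / K) if background is None
          else np.asarray(background, dtype=float))
    bg = bg / bg.sum()
    arr = msa.to_array()
    n_rows, n_cols = arr.shape
    is_gap = np.isin(arr, list(GAP_CHARS))
    gap_frac = is_gap.mean(axis=0)
    match_cols = np.flatnonzero(gap_frac < match_gap_fraction)
    M = len(match_cols)
    if M == 0:
        raise ValueError("no usable (match) columns in MSA")
    weights = henikoff_weights(arr, alphabet)
    lut = {c: i for i, c in enumerate(alphabet)}

    emit = np.tile(alpha * bg, (M, 1))
    denom = np.full(M, alpha)
    for mi, c in enumerate(match_cols):
        for r in range(n_rows):
            ch = arr[r, c]
            if ch in GAP_CHARS:
                continue
            code = lut.get(ch)
            if code is None:
                emit[mi] += weights[r] * bg
            else:
                emit[mi, code] += weights[r]
            denom[mi] += weights[r]
    emit /= denom[:, None]

    # transition counts from weighted state paths, row span only
    n_t = max(M - 1, 0)
    c_mm = np.full(n_t, trans_pseudo); c_mi = np.full(n_t, trans_pseudo)
    c_md = np.full(n_t, trans_pseudo); c_im = np.full(n_t, trans_pseudo)
    c_ii = np.full(n_t, trans_pseudo); c_dm = np.full(n_t, trans_pseudo)
    c_dd = np.full(n_t, trans_pseudo)
    col_kind = np.full(n_cols, -1)  # match-state index or -1 for insert col
    col_kind[match_cols] = np.arange(M)
    for r in range(n_rows):
        res_cols = np.flatnonzero(~is_gap[r])
        if res_cols.size == 0:
            continue
        lo, hi = res_cols[0], res_cols[-1]
        w = weights[r]
        prev = None  # (state kind, match index): kind in "M","I","D"
        for c in range(lo, hi + 1):
            k = col_kind[c]
            if k >= 0:
                cur = ("M", k) if not is_gap[r, c] else ("D", k)
            else:
                if is_gap[r, c]:
                    continue
                cur = ("I", None)
            if prev is not None:
                pk, pidx = prev
                if cur[0] == "I":
                    idx = pidx if pidx is not None else None
                    if pk == "M" and pidx is not None and pidx < M - 1:
                        c_mi[pidx] += w
                        cur = ("I", pidx)
                    elif pk == "I" and pidx is not None and pidx < M - 1:
                        c_ii[pidx] += w
                        cur = ("I", pidx)
                    else:
                        cur = ("I", pidx)
                else:
                    k2 = cur[1]
                    if pk == "M" and pidx is not None and pidx + 1 == k2:
                        (c_mm if cur[0] == "M" else c_md)[pidx] += w
                    elif pk == "D" and pidx is not None and pidx + 1 == k2:
                        (c_dm if cur[0] == "M" else c_dd)[pidx] += w
                    elif pk == "I" and pidx is not None and pidx + 1 == k2 \
                            and cur[0] == "M":
                        c_im[pidx] += w
            else:
                if cur[0] == "I":
                    cur = ("I", None)
            prev = cur

    eta = exit_prob if M > 1 else 1.0
    t_mm = np.zeros(M); t_mi = np.zeros(M); t_md = np.zeros(M)
    t_im = np.zeros(M); t_ii = np.zeros(M)
    t_dm = np.zeros(M); t_dd = np.zeros(M)
    t_me = np.zeros(M)
    t_me[M - 1] = 1.0
    for k in range(M - 1):
        into_last = (k == M - 2)
        me = eta
        if into_last:
            # no delete/insert dead ends into or past the final column
            tot = c_mm[k] + c_mi[k]
            t_mm[k] = (1 - me) * c_mm[k] / tot
            t_mi[k] = (1 - me) * c_mi[k] / tot
            t_md[k] = 0.0
            t_dm[k] = 1.0
            t_dd[k] = 0.0
        else:
            tot = c_mm[k] + c_mi[k] + c_md[k]
            t_mm[k] = (1 - me) * c_mm[k] / tot
            t_mi[k] = (1 - me) * c_mi[k] / tot
            t_md[k] = (1 - me) * c_md[k] / tot
            totd = c_dm[k] + c_dd[k]
            t_dm[k] = c_dm[k] / totd
            t_dd[k] = c_dd[k] / totd
        t_me[k] = me
        toti = c_im[k] + c_ii[k]
        t_im[k] = c_im[k] / toti
        t_ii[k] = c_ii[k] / toti

    master_positions = np.full(M, -1, dtype=np.int64)
    master = msa.master
    res_index = -1
    for c in range(n_cols):
        if master[c] not in GAP_CHARS:
            res_index += 1
        k = col_kind[c]
        if k >= 0 and master[c] not in GAP_CHARS:
            master_positions[k] = res_index
    hmm = ProfileHMM(
        name=name or msa.master_id, match_emit=emit, background=bg,
        t_mm=t_mm, t_mi=t_mi, t_md=t_md, t_im=t_im, t_ii=t_ii,
        t_dm=t_dm, t_dd=t_dd, t_me=t_me, alphabet=alphabet,
        master_positions=master_positions)
    hmm._cache["match_cols"] = match_cols
    hmm.validate()
    return hmm


def single_sequence_hmm(seq: str, alpha: float = DEFAULT_ALPHA,
                        background: np.ndarray | None = None,
                        alphabet: str = AMINO_ACIDS,
                        name: str = "query") -> ProfileHMM:
    """Profile HMM from a single ungapped sequence (iteration-0 query model)."""
    msa = MSA(ids=[name], rows=[seq], master_index=0)
    return hmm_from_msa(msa, alpha=alpha, background=background,
                        alphabet=alphabet, name=name)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def forward_score(hmm: ProfileHMM, seq: str) -> float:
    """log2-odds of the sequence under the local model vs background (bits)."""
    if len(seq) == 0:
        raise ValueError("empty sequence")
    codes = hmm.encode(seq)
    return float(_kernels.forward_logodds(hmm.kernel_args()[0], codes,
                                          *hmm.kernel_args()[1:]) / LN2)


def viterbi_align(hmm: ProfileHMM, seq: str):
    """Best path score (bits) and trace of (seq position, match state), 1-based."""
    if len(seq) == 0:
        raise ValueError("empty sequence")
    codes = hmm.encode(seq)
    score, pairs = _kernels.viterbi_trace(hmm.kernel_args()[0], codes,
                                          *hmm.kernel_args()[1:])
    trace = [(int(i) + 1, int(k) + 1) for i, k in pairs]
    return float(score / LN2), trace


def viterbi_score_many(hmm: ProfileHMM, seqs) -> np.ndarray:
    """Viterbi scores (bits) for a list of sequences (strings or code arrays)."""
    codes = [s if isinstance(s, np.ndarray) else hmm.encode(s) for s in seqs]
    flat = np.concatenate(codes) if codes else np.zeros(0, dtype=np.int64)
    offsets = np.zeros(len(codes) + 1, dtype=np.int64)
    np.cumsum([len(c) for c in codes], out=offsets[1:])
    if any(len(c) == 0 for c in codes):
        raise ValueError("empty sequence in batch")
    ka = hmm.kernel_args()
    return _kernels.viterbi_scores_batch(ka[0], flat, offsets, *ka[1:]) / LN2


def coemission_scores(hmm_q: ProfileHMM, hmm_t: ProfileHMM) -> np.ndarray:
    """Column co-emission log-odds matrix S(i,j) in bits."""
    if hmm_q.alphabet != hmm_t.alphabet:
        raise ValueError("profiles must share an alphabet")
    odds_t = hmm_t._cache.get("odds_T")
    if odds_t is None:
        odds_t = np.ascontiguousarray((hmm_t.match_emit / hmm_t.background).T)
        hmm_t._cache["odds_T"] = odds_t
    inner = hmm_q.match_emit @ odds_t
    return np.log2(np.maximum(inner, 1e-300))


def hmm_hmm_align(hmm_q: ProfileHMM, hmm_t: ProfileHMM,
                  gap_open: float = DEFAULT_GAP_OPEN,
                  gap_extend: float = DEFAULT_GAP_EXTEND):
    """Local profile-profile alignment over match-column pairs.

    Returns ``(bits, pairing)`` where pairing lists aligned (query column,
    target column) pairs, 1-based.  With symmetric gap costs the score is
    symmetric in its arguments.
    """
    S = coemission_scores(hmm_q, hmm_t)
    score, pairs = _kernels.local_affine_align(S, gap_open, gap_extend)
    return float(score), [(int(i) + 1, int(j) + 1) for i, j in pairs]


def hmm_hmm_score(hmm_q: ProfileHMM, hmm_t: ProfileHMM,
                  gap_open: float = DEFAULT_GAP_OPEN,
                  gap_extend: float = DEFAULT_GAP_EXTEND) -> float:
    """Score-only profile-profile alignment (same result as hmm_hmm_align)."""
    S = coemission_scores(hmm_q, hmm_t)
    return float(_kernels.local_affine_score(S, gap_open, gap_extend))


# ---------------------------------------------------------------------------
# E-value calibration and search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EVDParams:
    """Gumbel tail fit: E(s) = n_db * (1 - exp(-exp(-lambda*(s - mu))))."""

    lam: float
    mu: float
    n_db: int = 1

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.n_db < 1:
            raise ValueError("n_db must be >= 1")

    def pvalue(self, score) -> np.ndarray:
        return gumbel_r.sf(score, loc=self.mu, scale=1.0 / self.lam)

    def evalue(self, score) -> np.ndarray:
        return self.n_db * self.pvalue(score)

    def with_n_db(self, n_db: int) -> "EVDParams":
        return EVDParams(self.lam, self.mu, n_db)


def fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Gumbel fit; returns (lambda, mu)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 10:
        raise ValueError("need at least 10 scores to fit")
    if np.ptp(scores) == 0:
        raise ValueError("degenerate (constant) decoy scores")
    loc, scale = gumbel_r.fit(scores)
    return 1.0 / scale, float(loc)


def background_decoy_sampler(lengths, background: np.ndarray | None = None,
                             alphabet: str = AMINO_ACIDS):
    """Decoy sampler: i.i.d. background sequences, lengths resampled from
    the supplied length pool (e.g. the target database).

    Returns encoded integer arrays (accepted everywhere sequences are
    scored) to avoid string round-trips in hot loops.
    """
    lengths = np.asarray(list(lengths), dtype=np.int64)
    if lengths.size == 0 or lengths.min() < 1:
        raise ValueError("decoy length pool must be non-empty and positive")
    k = len(alphabet)
    bg = (np.full(k, 1.0 / k) if background is None
          else np.asarray(background, dtype=float))
    bg = bg / bg.sum()

    def sampler(rng: np.random.Generator, n: int):
        ls = rng.choice(lengths, size=n)
        flat = rng.choice(k, size=int(ls.sum()), p=bg)
        out = []
        pos = 0
        for L in ls:
            out.append(flat[pos:pos + int(L)].astype(np.int64))
            pos += int(L)
        return out

    return sampler


def calibrate_evd(hmm: ProfileHMM, decoy_sampler, n_decoys: int = 200,
                  seed: int = 0, n_db: int = 1,
                  score_fn=None) -> EVDParams:
    """Fit Gumbel parameters to decoy optimal-alignment scores.

    ``decoy_sampler(rng, n)`` returns background sequences (or decoy
    profiles, with a matching ``score_fn``).  Deterministic under ``seed``.
    """
    if n_decoys < 10:
        raise ValueError("n_decoys too small for a stable fit")
    rng = np.random.default_rng(seed)
    decoys = decoy_sampler(rng, n_decoys)
    if score_fn is None:
        scores = viterbi_score_many(hmm, decoys)
    else:
        scores = np.array([score_fn(hmm, d) for d in decoys])
    lam, mu = fit_gumbel(scores)
    return EVDParams(lam=lam, mu=mu, n_db=n_db)


@dataclass(frozen=True)
class SearchHit:
    """A scored query-target alignment."""

    query_id: str
    target_id: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    score: float       # bits
    evalue: float
    trace: tuple = ()

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("E-value must be >= 0")
        if self.q_start > self.q_end or self.t_start > self.t_end:
            raise ValueError("invalid hit interval")


def search(query_hmm: ProfileHMM, targets, evd: EVDParams,
           e_max: float = 0.01) -> list[SearchHit]:
    """Score a target set and return hits with E <= e_max.

    ``targets`` is a list of ``(id, sequence)`` or ``(id, ProfileHMM)``.
    Hits are sorted by ascending E-value, ties broken by target id; intervals
    come from the Viterbi trace (sequence targets: query interval in match
    states, target interval in residues) or the profile-profile column
    pairing.
    """
    targets = list(targets)
    if not targets:
        return []
    hits: list[SearchHit] = []
    profile_mode = isinstance(targets[0][1], ProfileHMM)
    if profile_mode:
        for tid, thmm in targets:
            score, pairs = hmm_hmm_align(query_hmm, thmm)
            ev = float(evd.evalue(score))
            if ev <= e_max and pairs:
                hits.append(SearchHit(
                    query_id=query_hmm.name, target_id=tid,
                    q_start=pairs[0][0], q_end=pairs[-1][0],
                    t_start=pairs[0][1], t_end=pairs[-1][1],
                    score=score, evalue=ev, trace=tuple(pairs)))
    else:
        seqs = [s for _, s in targets]
        scores = viterbi_score_many(query_hmm, seqs)
        evs = evd.evalue(scores)
        for (tid, seq), score, ev in zip(targets, scores, evs):
            if ev <= e_max:
                vscore, trace = viterbi_align(query_hmm, seq)
                if not trace:
                    continue
                hits.append(SearchHit(
                    query_id=query_hmm.name, target_id=tid,
                    q_start=trace[0][1], q_end=trace[-1][1],
                    t_start=trace[0][0], t_end=trace[-1][0],
                    score=float(vscore), evalue=float(ev), trace=tuple(trace)))
    hits.sort(key=lambda h: (h.evalue, h.target_id))
    return hits


# ---------------------------------------------------------------------------
# Plain-text profile serialization (HMMER-inspired layout)
# ---------------------------------------------------------------------------

def write_profile(hmm: ProfileHMM, path) -> None:
    with open(path, "w") as fh:
        fh.write("GMDOM-HMM 1\n")
        fh.write(f"NAME {hmm.name}\n")
        fh.write(f"ALPH {hmm.alphabet}\n")
        fh.write(f"LENG {hmm.n_match}\n")
        fh.write("BG " + " ".join(f"{x:.8e}" for x in hmm.background) + "\n")
        if hmm.master_positions is not None:
            fh.write("MAP " + " ".join(str(int(x)) for x in hmm.master_positions) + "\n")
        for k in range(hmm.n_match):
            fh.write(f"M {k + 1} "
                     + " ".join(f"{x:.8e}" for x in hmm.match_emit[k]) + "\n")
            fh.write("T {} {:.8e} {:.8e} {:.8e} {:.8e} {:.8e} {:.8e} {:.8e} {:.8e}\n"
                     .format(k + 1, hmm.t_mm[k], hmm.t_mi[k], hmm.t_md[k],
                             hmm.t_im[k], hmm.t_ii[k], hmm.t_dm[k],
                             hmm.t_dd[k], hmm.t_me[k]))
        fh.write("//\n")


def read_profile(path) -> ProfileHMM:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or not lines[0].startswith("GMDOM-HMM"):
        raise ValueError("not a gmdomains profile file")
    name, alphabet, M, bg, mp = "", AMINO_ACIDS, 0, None, None
    emit_rows, trows = {}, {}
    for ln in lines[1:]:
        if ln == "//" or not ln:
            continue
        tag, rest = ln.split(" ", 1)
        if tag == "NAME":
            name = rest
        elif tag == "ALPH":
            alphabet = rest
        elif tag == "LENG":
            M = int(rest)
        elif tag == "BG":
            bg = np.array([float(x) for x in rest.split()])
        elif tag == "MAP":
            mp = np.array([int(x) for x in rest.split()], dtype=np.int64)
        elif tag == "M":
            parts = rest.split()
            emit_rows[int(parts[0]) - 1] = [float(x) for x in parts[1:]]
        elif tag == "T":
            parts = rest.split()
            trows[int(parts[0]) - 1] = [float(x) for x in parts[1:]]
    emit = np.array([emit_rows[k] for k in range(M)])
    T = np.array([trows[k] for k in range(M)])
    hmm = ProfileHMM(name=name, match_emit=emit, background=bg,
                     t_mm=T[:, 0], t_mi=T[:, 1], t_md=T[:, 2], t_im=T[:, 3],
                     t_ii=T[:, 4], t_dm=T[:, 5], t_dd=T[:, 6], t_me=T[:, 7],
                     alphabet=alphabet, master_positions=mp)
    hmm.validate(tol=1e-6)
    return hmm


def hits_to_tsv(hits, path) -> None:
    import pandas as pd
    pd.DataFrame(
        [(h.query_id, h.target_id, h.q_start, h.q_end, h.t_start, h.t_end,
          round(h.score, 4), h.evalue) for h in hits],
        columns=["query", "target", "q_start", "q_end", "t_start", "t_end",
                 "bits", "E"]).to_csv(path, sep="\t", index=False)
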