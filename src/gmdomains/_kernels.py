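"""Numba dynamic-programming kernels for the profile-HMM engine.

All kernels work in natural-log space over a local-alignment profile HMM with
M match states: entry into any match state at any sequence position with
probability ``1 / (M * L)``, per-state exit probabilities carried in ``lme``,
and the usual M/I/D transition structure between consecutive positions.
Insert states emit background (log-odds 0); delete states emit nothing.
Emission log-odds tables have 21 columns (20 residues + a neutral column for
non-canonical codes).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1.0e30


@njit(cache=True, fastmath=False)
def _lse2(a, b):
    if a < b:
        a, b = b, a
    if a <= NEG_INF / 2:
        return a
    return a + np.log1p(np.exp(b - a))


@njit(cache=True)
def forward_logodds(lo, seq, lmm, lmi, lmd, lim, lii, ldm, ldd, lme):
    """Forward log-odds (natural log) of a sequence under the local model."""
    M = lo.shape[0]
    L = seq.shape[0]
    lb = -np.log(M * 1.0) - np.log(L * 1.0)
    fM = np.full((L, M), NEG_INF)
    fI = np.full((L, M), NEG_INF)
    fD = np.full((L, M), NEG_INF)
    total = NEG_INF
    for i in range(L):
        for k in range(M):
            acc = lb
            if i > 0 and k > 0:
                acc = _lse2(acc, fM[i - 1, k - 1] + lmm[k - 1])
                acc = _lse2(acc, fI[i - 1, k - 1] + lim[k - 1])
                acc = _lse2(acc, fD[i - 1, k - 1] + ldm[k - 1])
            fM[i, k] = lo[k, seq[i]] + acc
            total = _lse2(total, fM[i, k] + lme[k])
        if i > 0:
            for k in range(M - 1):
                fI[i, k] = _lse2(fM[i - 1, k] + lmi[k], fI[i - 1, k] + lii[k])
        for k in range(1, M):
            fD[i, k] = _lse2(fM[i, k - 1] + lmd[k - 1], fD[i, k - 1] + ldd[k - 1])
    return total


@njit(cache=True, fastmath=True)
def _viterbi_score_t(loT, seq, lmm, lmi, lmd, lim, lii, ldm, ldd, lme):
    """Score-only Viterbi with transposed emissions loT (n_letters+1, M)
    and rolling one-dimensional state arrays."""
    M = loT.shape[1]
    L = seq.shape[0]
    lb = -np.log(M * 1.0) - np.log(L * 1.0)
    pM = np.full(M, NEG_INF)
    pI = np.full(M, NEG_INF)
    cM = np.full(M, NEG_INF)
    cI = np.full(M, NEG_INF)
    cD = np.full(M, NEG_INF)
    best = NEG_INF
    for i in range(L):
        c = seq[i]
        erow = loT[c]
        cM[0] = erow[0] + lb
        x = cM[0] + lme[0]
        if x > best:
            best = x
        for k in range(1, M):
            acc = lb
            v = pM[k - 1] + lmm[k - 1]
            if v > acc:
                acc = v
            v = pI[k - 1] + lim[k - 1]
            if v > acc:
                acc = v
            v = cD[k - 1] + ldm[k - 1]  # cD here still holds row i-1 value
            if v > acc:
                acc = v
            cM[k] = erow[k] + acc
            x = cM[k] + lme[k]
            if x > best:
                best = x
        if i > 0:
            for k in range(M - 1):
                a = pM[k] + lmi[k]
                b = pI[k] + lii[k]
                cI[k] = a if a > b else b
        # delete row for position i (used by match row i+1)
        cD[0] = NEG_INF
        for k in range(1, M):
            a = cM[k - 1] + lmd[k - 1]
            b = cD[k - 1] + ldd[k - 1]
            cD[k] = a if a > b else b
        pM, cM = cM, pM
        pI, cI = cI, pI
    return best


@njit(cache=True)
def viterbi_score(lo, seq, lmm, lmi, lmd, lim, lii, ldm, ldd, lme):
    """Best-path log-odds (natural log); score only, no traceback."""
    loT = np.ascontiguousarray(lo.T)
    return _viterbi_score_t(loT, seq, lmm, lmi, lmd, lim, lii, ldm, ldd, lme)


@njit(cache=True)
def viterbi_scores_batch(lo, seqs_flat, offsets,
                         lmm, lmi, lmd, lim, lii, ldm, ldd, lme):
    """Viterbi scores for many sequences (concatenated with offsets)."""
    loT = np.ascontiguousarray(lo.T)
    n = offsets.shape[0] - 1
    out = np.empty(n)
    for t in range(n):
        out[t] = _viterbi_score_t(loT, seqs_flat[offsets[t]:offsets[t + 1]],
                                  lmm, lmi, lmd, lim, lii, ldm, ldd, lme)
    return out


@njit(cache=True)
def viterbi_trace(lo, seq, lmm, lmi, lmd, lim, lii, ldm, ldd, lme):
    """Viterbi with traceback.

    Returns ``(score, pairs)`` where ``pairs`` is an (n, 2) int64 array of
    (sequence position, match state), both 0-based, for every match emission
    on the optimal path, in increasing order.
    """
    M = lo.shape[0]
    L = seq.shape[0]
    lb = -np.log(M * 1.0) - np.log(L * 1.0)
    vM = np.full((L, M), NEG_INF)
    vI = np.full((L, M), NEG_INF)
    vD = np.full((L, M), NEG_INF)
    pM = np.zeros((L, M), dtype=np.int8)   # 0=begin 1=MM 2=IM 3=DM
    pI = np.zeros((L, M), dtype=np.int8)   # 0=MI 1=II
    pD = np.zeros((L, M), dtype=np.int8)   # 0=MD 1=DD
    best = NEG_INF
    bi = -1
    bk = -1
    for i in range(L):
        for k in range(M):
            acc = lb
            ptr = 0
            if i > 0 and k > 0:
                x = vM[i - 1, k - 1] + lmm[k - 1]
                if x > acc:
                    acc = x
                    ptr = 1
                x = vI[i - 1, k - 1] + lim[k - 1]
                if x > acc:
                    acc = x
                    ptr = 2
                x = vD[i - 1, k - 1] + ldm[k - 1]
                if x > acc:
                    acc = x
                    ptr = 3
            vM[i, k] = lo[k, seq[i]] + acc
            pM[i, k] = ptr
            if vM[i, k] + lme[k] > best:
                best = vM[i, k] + lme[k]
                bi = i
                bk = k
        if i > 0:
            for k in range(M - 1):
                a = vM[i - 1, k] + lmi[k]
                b = vI[i - 1, k] + lii[k]
                if a >= b:
                    vI[i, k] = a
                    pI[i, k] = 0
                else:
                    vI[i, k] = b
                    pI[i, k] = 1
        for k in range(1, M):
            a = vM[i, k - 1] + lmd[k - 1]
            b = vD[i, k - 1] + ldd[k - 1]
            if a >= b:
                vD[i, k] = a
                pD[i, k] = 0
            else:
                vD[i, k] = b
                pD[i, k] = 1
    pairs = np.empty((L, 2), dtype=np.int64)
    n_pairs = 0
    if bi >= 0:
        i = bi
        k = bk
        state = 0  # 0=M 1=I 2=D
        while True:
            if state == 0:
                pairs[n_pairs, 0] = i
                pairs[n_pairs, 1] = k
                n_pairs += 1
                ptr = pM[i, k]
                if ptr == 0:
                    break
                elif ptr == 1:
                    i -= 1
                    k -= 1
                    state = 0
                elif ptr == 2:
                    i -= 1
                    k -= 1
                    state = 1
                else:
                    i -= 1
                    k -= 1
                    state = 2
            elif state == 1:
                ptr = pI[i, k]
                i -= 1
                state = 0 if ptr == 0 else 1
            else:
                ptr = pD[i, k]
                if ptr == 0:
                    state = 0
                    k -= 1
                else:
                    k -= 1
                    state = 2
    out = pairs[:n_pairs][::-1].copy()
    return best, out


@njit(cache=True, fastmath=True)
def local_affine_score(S, gap_open, gap_extend):
    """Score-only Smith-Waterman with affine gaps (rolling arrays)."""
    n, m = S.shape
    pH = np.zeros(m + 1)
    pX = np.full(m + 1, NEG_INF)
    pY = np.full(m + 1, NEG_INF)
    cH = np.zeros(m + 1)
    cX = np.full(m + 1, NEG_INF)
    cY = np.full(m + 1, NEG_INF)
    best = 0.0
    for i in range(1, n + 1):
        cH[0] = 0.0
        cX[0] = NEG_INF
        cY[0] = NEG_INF
        for j in range(1, m + 1):
            a = pH[j] - gap_open
            b = pX[j] - gap_extend
            cX[j] = a if a >= b else b
            a = cH[j - 1] - gap_open
            b = cY[j - 1] - gap_extend
            cY[j] = a if a >= b else b
            v = 0.0
            if pH[j - 1] > v:
                v = pH[j - 1]
            if pX[j - 1] > v:
                v = pX[j - 1]
            if pY[j - 1] > v:
                v = pY[j - 1]
            v += S[i - 1, j - 1]
            if v < 0.0:
                v = 0.0
            cH[j] = v
            if v > best:
                best = v
        pH, cH = cH, pH
        pX, cX = cX, pX
        pY, cY = cY, pY
    return best


@njit(cache=True)
def local_affine_align(S, gap_open, gap_extend):
    """Local (Smith-Waterman) alignment with affine gaps over a score matrix.

    ``S[i, j]`` is the pair score (bits) for matching row i to column j.
    Returns ``(score, pairs)`` with the aligned (i, j) index pairs of the
    best-scoring local path (matched cells only).
    """
    n, m = S.shape
    H = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), NEG_INF)   # gap in rows (i advances)
    Y = np.full((n + 1, m + 1), NEG_INF)   # gap in cols (j advances)
    pH = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0=start 1=H 2=X 3=Y
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0=H 1=X
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            a = H[i - 1, j] - gap_open
            b = X[i - 1, j] - gap_extend
            if a >= b:
                X[i, j] = a
                pX[i, j] = 0
            else:
                X[i, j] = b
                pX[i, j] = 1
            a = H[i, j - 1] - gap_open
            b = Y[i, j - 1] - gap_extend
            if a >= b:
                Y[i, j] = a
                pY[i, j] = 0
            else:
                Y[i, j] = b
                pY[i, j] = 1
            v = 0.0
            ptr = 0
            if H[i - 1, j - 1] > v:
                v = H[i - 1, j - 1]
                ptr = 1
            if X[i - 1, j - 1] > v:
                v = X[i - 1, j - 1]
                ptr = 2
            if Y[i - 1, j - 1] > v:
                v = Y[i - 1, j - 1]
                ptr = 3
            v += S[i - 1, j - 1]
            if v < 0.0:
                v = 0.0
                ptr = 0
            H[i, j] = v
            pH[i, j] = ptr
            if v > best:
                best = v
                bi = i
                bj = j
    pairs = np.empty((n + m, 2), dtype=np.int64)
    n_pairs = 0
    if best > 0.0:
        i = bi
        j = bj
        state = 0
        while i > 0 and j > 0:
            if state == 0:
                pairs[n_pairs, 0] = i - 1
                pairs[n_pairs, 1] = j - 1
                n_pairs += 1
                ptr = pH[i, j]
                i -= 1
                j -= 1
                if ptr == 0:
                    break
                state = 0 if ptr == 1 else (1 if ptr == 2 else 2)
            elif state == 1:
                ptr = pX[i, j]
                i -= 1
                state = 0 if ptr == 0 else 1
            else:
                ptr = pY[i, j]
                j -= 1
                state = 0 if ptr == 0 else 2
    out = pairs[:n_pairs][::-1].copy()
    return best, out
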