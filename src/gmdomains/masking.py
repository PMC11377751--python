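"""Coiled-coil and low-complexity masking of search queries.

Remote-homology profiles are easily corrupted by coiled-coil heptad repeats
and compositionally biased tracts, which produce spurious matches between
unrelated proteins.  Queries are therefore scanned with a COILS-style
sliding-window heptad propensity score and a windowed Shannon-entropy
statistic, and only the mask-free regions enter the searches.

The 20x7 position-specific propensity table used here is a documented
synthetic stand-in derived from helix/coiled-coil residue propensities (the
original COILS distribution matrix is not redistributed with this package);
all scores are therefore meaningful relatively (coiled coil vs globular), not
as absolute COILS probabilities, and every test of this module is
property-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .alphabet import AMINO_ACIDS, encode

logger = logging.getLogger(__name__)

HEPTAD_WINDOWS = (14, 21, 28)
AD_WEIGHT = 2.5  # up-weighting of heptad positions a and d in the weighted scan

# ---------------------------------------------------------------------------
# Synthetic stand-in propensity table (residues x heptad positions a..g).
# Position a = 0, d = 3 favour the aliphatic/hydrophobic seam; b,c,e,f,g
# favour charged/polar helix formers.  Proline is strongly disfavoured at
# every position, glycine weakly.
# ---------------------------------------------------------------------------

_HYDRO = {"L": 6.0, "I": 4.5, "M": 4.0, "V": 3.5, "F": 3.0, "A": 2.0,
          "W": 0.8, "Y": 0.8, "C": 0.6, "E": 0.35, "K": 0.35, "Q": 0.35,
          "R": 0.35, "S": 0.35, "N": 0.35, "D": 0.3, "T": 0.35, "H": 0.4,
          "G": 0.25, "P": 0.05}
_POLAR = {"E": 2.5, "K": 2.2, "Q": 2.0, "R": 1.9, "A": 1.6, "L": 0.8,
          "S": 1.1, "N": 1.2, "D": 1.2, "T": 0.9, "M": 0.8, "I": 0.5,
          "V": 0.5, "F": 0.5, "H": 1.0, "W": 0.5, "Y": 0.7, "C": 0.6,
          "G": 0.9, "P": 0.05}

PROPENSITY = np.zeros((21, 7))
for _i, _aa in enumerate(AMINO_ACIDS):
    for _pos in range(7):
        PROPENSITY[_i, _pos] = _HYDRO[_aa] if _pos in (0, 3) else _POLAR[_aa]
PROPENSITY[20, :] = 1.0  # unknown residues are neutral
_LOG_PROP = np.log(PROPENSITY)

# Two-population Gaussian model of the window score (geometric-mean
# propensity): coiled-coil vs globular, with a prior odds weight on the
# globular class.  Parameters were calibrated once on ensembles of ideal
# heptad repeats and of i.i.d. background sequence and are frozen here;
# keys are (window, weighted).
GAUSSIAN_PARAMS = {
    (14, False): (2.2877, 0.1444, 1.2672, 0.2112),
    (14, True): (2.7739, 0.1849, 1.4534, 0.3158),
    (21, False): (2.2614, 0.1178, 1.1728, 0.1654),
    (21, True): (2.7464, 0.1426, 1.3039, 0.2341),
    (28, False): (2.2427, 0.0987, 1.1120, 0.1418),
    (28, True): (2.7332, 0.1301, 1.2131, 0.1936),
}
GLOBULAR_PRIOR_WEIGHT = 30.0


@dataclass(frozen=True)
class MaskedRegion:
    """A masked residue interval, 1-based inclusive."""

    start: int
    end: int
    kind: str  # "coiled_coil" or "low_complexity"
    score: float

    def __post_init__(self):
        if self.start > self.end or self.start < 1:
            raise ValueError("invalid masked region bounds")


def coiled_coil_profile(seq: str, window: int = 21,
                        weighted: bool = False,
                        raw: bool = False) -> np.ndarray:
    """Per-residue coiled-coil probability in [0, 1].

    For each of the 7 heptad frames, each window of ``window`` residues is
    scored by the (weighted) geometric mean of the position-specific
    propensities; each residue takes the maximum score over the frames and
    windows covering it, and the score is converted to a probability by a
    two-Gaussian (coiled-coil vs globular) posterior.  The weighted variant
    up-weights heptad positions a and d by ``AD_WEIGHT``.  With ``raw=True``
    the geometric-mean propensity itself is returned (useful for relative
    comparisons where the posterior saturates).
    """
    if window not in HEPTAD_WINDOWS:
        raise ValueError(f"window must be one of {HEPTAD_WINDOWS}")
    n = len(seq)
    if n < window:
        logger.warning("sequence shorter than window (%d < %d): empty profile",
                       n, window)
        return np.zeros(0)
    codes = encode(seq)
    best = np.full(n, -np.inf)
    n_win = n - window + 1
    idx = np.arange(n)
    for frame in range(7):
        heptad_pos = (idx + frame) % 7
        logp = _LOG_PROP[codes, heptad_pos]
        w = np.where((heptad_pos == 0) | (heptad_pos == 3), AD_WEIGHT, 1.0) \
            if weighted else np.ones(n)
        cs_wl = np.concatenate([[0.0], np.cumsum(w * logp)])
        cs_w = np.concatenate([[0.0], np.cumsum(w)])
        win_score = ((cs_wl[window:] - cs_wl[:-window])
                     / (cs_w[window:] - cs_w[:-window]))
        for off in range(window):
            seg = best[off:off + n_win]
            np.maximum(seg, win_score[:len(seg)], out=seg)
    score = np.exp(best)
    if raw:
        return score
    mcc, scc, mg, sg = GAUSSIAN_PARAMS[(window, weighted)]
    gcc = np.exp(-0.5 * ((score - mcc) / scc) ** 2) / scc
    gg = np.exp(-0.5 * ((score - mg) / sg) ** 2) / sg
    return gcc / (gcc + GLOBULAR_PRIOR_WEIGHT * gg)


def _merge_mask(mask: np.ndarray, kind: str,
                scores: np.ndarray) -> list[MaskedRegion]:
    regions = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            stat = scores[i:j + 1]
            score = float(stat.max()) if kind == "coiled_coil" else float(stat.min())
            regions.append(MaskedRegion(i + 1, j + 1, kind, score))
            i = j + 1
        else:
            i += 1
    return regions


def coiled_coil_mask(seq: str, window: int = 21, weighted: bool = True,
                     probability_cutoff: float = 0.5) -> list[MaskedRegion]:
    """Mask residues with coiled-coil probability >= ``probability_cutoff``."""
    prob = coiled_coil_profile(seq, window=window, weighted=weighted)
    if prob.size == 0:
        return []
    return _merge_mask(prob >= probability_cutoff, "coiled_coil", prob)


def low_complexity_mask(seq: str, window: int = 12,
                        entropy_threshold: float = 2.2) -> list[MaskedRegion]:
    """Mask residues whose minimum covering-window Shannon entropy is low.

    Entropy is computed in bits over the residue frequencies of each
    ``window``-mer; a residue is masked when the minimum entropy over the
    windows covering it falls below ``entropy_threshold``.  Sequences shorter
    than the window are treated as a single window.
    """
    n = len(seq)
    if n == 0:
        return []
    codes = encode(seq)
    win = min(window, n)
    onehot = np.zeros((n, 21))
    onehot[np.arange(n), codes] = 1.0
    cs = np.concatenate([np.zeros((1, 21)), np.cumsum(onehot, axis=0)])
    counts = cs[win:] - cs[:-win]          # (n_win, 21)
    freq = counts / win
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.nansum(np.where(freq > 0, freq * np.log2(freq), 0.0), axis=1)
    min_ent = np.full(n, np.inf)
    n_win = n - win + 1
    for off in range(win):
        seg = min_ent[off:off + n_win]
        np.minimum(seg, ent[:len(seg)], out=seg)
    return _merge_mask(min_ent < entropy_threshold, "low_complexity", min_ent)


def searchable_regions(seq: str, masks, min_region_length: int = 20) -> list:
    """Complement of the mask union, as sorted 1-based inclusive intervals.

    Fragments shorter than ``min_region_length`` are dropped (logged); a
    fully masked sequence yields an empty list and is logged as a skipped
    query.
    """
    n = len(seq)
    covered = np.zeros(n, dtype=bool)
    for m in masks:
        if m.end > n:
            raise ValueError("mask exceeds sequence bounds")
        covered[m.start - 1:m.end] = True
    regions = []
    i = 0
    while i < n:
        if not covered[i]:
            j = i
            while j + 1 < n and not covered[j + 1]:
                j += 1
            if j - i + 1 >= min_region_length:
                regions.append((i + 1, j + 1))
            else:
                logger.info("dropping short searchable fragment (%d, %d)",
                            i + 1, j + 1)
            i = j + 1
        else:
            i += 1
    if not regions:
        logger.warning("sequence fully masked; query skipped")
    return regions


def mask_sequence(seq: str, window: int = 21, weighted: bool = True,
                  probability_cutoff: float = 0.5,
                  lc_window: int = 12, entropy_threshold: float = 2.2):
    """Convenience: both masks plus the resulting searchable regions."""
    masks = (coiled_coil_mask(seq, window, weighted, probability_cutoff)
             + low_complexity_mask(seq, lc_window, entropy_threshold))
    return masks, searchable_regions(seq, masks)


def masks_to_bed(masks_by_id: dict, path) -> None:
    """Write masks as BED-like TSV (0-based half-open, converted here)."""
    import pandas as pd
    rows = [(sid, m.start - 1, m.end, m.kind, round(m.score, 4))
            for sid in sorted(masks_by_id) for m in masks_by_id[sid]]
    pd.DataFrame(rows, columns=["seq_id", "start", "end", "kind", "score"]).to_csv(
        path, sep="\t", index=False)
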