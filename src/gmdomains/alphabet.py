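"""Amino-acid alphabet and background composition shared by simulation and scoring.

A single background frequency vector is used by the sequence generators, the
profile-HMM null model, and the masking statistics, so that the odds scored by
the search engine are exactly the odds the simulator planted.
"""

from __future__ import annotations

import numpy as np

#: The 20 canonical residues, in the fixed internal order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residues accepted in input but carrying no information for scoring
#: (ambiguity / rare codes); they are emitted as background, never an error.
NONCANONICAL = "BZXUO"

#: Integer code assigned to any non-canonical residue.
UNKNOWN_CODE = 20

#: Default background: uniform over the 20 canonical residues.
UNIFORM_BACKGROUND = np.full(20, 0.05)

_CODE = np.full(128, UNKNOWN_CODE, dtype=np.int64)
for _i, _aa in enumerate(AMINO_ACIDS):
    _CODE[ord(_aa)] = _i
    _CODE[ord(_aa.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as integer codes 0..19; unknown residues become 20.

    Gap characters are not allowed here — encode ungapped sequences only.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    if np.any((arr == ord("-")) | (arr == ord("."))):
        raise ValueError("encode() expects an ungapped sequence")
    return _CODE[arr]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`; unknown codes render as 'X'."""
    return "".join(AMINO_ACIDS[c] if c < 20 else "X" for c in codes)


def random_sequence(length: int, rng: np.random.Generator,
                    background: np.ndarray | None = None) -> str:
    """Draw an i.i.d. sequence from the background composition."""
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background)
    codes = rng.choice(20, size=length, p=bg / bg.sum())
    return "".join(AMINO_ACIDS[c] for c in codes)
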