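"""DNA alphabet encoding shared by the motif-model and search machinery.

Sequences are stored as small integer arrays: A=0, C=1, G=2, T=3, N=4.
Dinucleotides are encoded as ``4*first + second`` (AA=0 .. TT=15); a pair
touching an 'N' gets the sentinel code 16 and a padding "no pair" slot uses
17.  Ambiguous symbols never carry information: their *contribution rows*
spread one unit of count mass uniformly over the concrete symbols, so every
tally stays total without inventing IUPAC semantics.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
N_CODE = 4
DINUCLEOTIDES = tuple(a + b for a in BASES for b in BASES)

PAIR_N_CODE = 16  # pair with at least one N
PAIR_NULL_CODE = 17  # out-of-range padding; contributes nothing

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_BASE_INDEX["N"] = N_CODE

_ENCODE_LUT = np.full(256, -1, dtype=np.int8)
for _ch, _ix in _BASE_INDEX.items():
    _ENCODE_LUT[ord(_ch)] = _ix
    _ENCODE_LUT[ord(_ch.lower())] = _ix

# contribution rows: one unit of count mass per symbol occurrence
MONO_CONTRIB = np.zeros((5, 4))
MONO_CONTRIB[:4] = np.eye(4)
MONO_CONTRIB[N_CODE] = 0.25

PAIR_CONTRIB = np.zeros((18, 16))
PAIR_CONTRIB[:16] = np.eye(16)
PAIR_CONTRIB[PAIR_N_CODE] = 1.0 / 16.0
# PAIR_NULL_CODE row stays all-zero

_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.int8)


def encode(seq: str) -> np.ndarray:
    """Encode an A/C/G/T/N string (any case) as an int8 array.

    Raises ``ValueError`` naming the offending offset for other characters.
    """
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    enc = _ENCODE_LUT[raw]
    bad = np.nonzero(enc < 0)[0]
    if bad.size:
        off = int(bad[0])
        raise ValueError(f"illegal character {seq[off]!r} at offset {off}")
    return enc.astype(np.int8)


def decode(enc: np.ndarray) -> str:
    return "".join("ACGTN"[i] for i in enc)


def reverse_complement(enc: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[enc[::-1]]


def pair_codes(enc: np.ndarray) -> np.ndarray:
    """Dinucleotide codes for every adjacent position pair (length L-1)."""
    if enc.size < 2:
        return np.empty(0, dtype=np.int16)
    a = enc[:-1].astype(np.int16)
    b = enc[1:].astype(np.int16)
    codes = 4 * a + b
    codes[(a == N_CODE) | (b == N_CODE)] = PAIR_N_CODE
    return codes


def padded_pair_codes(enc: np.ndarray) -> np.ndarray:
    """Pair codes indexed by u = t + 1 with null sentinels at both ends.

    ``padded[u]`` is the code of the pair starting at position ``u - 1``;
    u = 0 and u = L are padding.  Lets fixed-width sliding windows over pair
    positions clip cleanly at sequence boundaries.
    """
    out = np.full(enc.size + 1, PAIR_NULL_CODE, dtype=np.int16)
    out[1 : enc.size] = pair_codes(enc)
    return out
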