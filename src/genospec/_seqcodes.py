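"""Integer encoding of nucleotide strings shared across modules.

A,C,G,T -> 0..3; '-' -> 4; N -> 5. The 0..3 codes are chosen so that a
transition (A<->G, C<->T) flips bit 1 (code XOR 2), which makes
transition/transversion classification a single vectorised XOR.
"""

from __future__ import annotations

import numpy as np

A, C, G, T, GAP, N = 0, 1, 2, 3, 4, 5

_LUT = np.full(256, N, dtype=np.uint8)
for ch, code in zip(b"ACGT-N", (A, C, G, T, GAP, N)):
    _LUT[ch] = code
_LUT[ord("a")] = A
_LUT[ord("c")] = C
_LUT[ord("g")] = G
_LUT[ord("t")] = T
_LUT[ord("U")] = T
_LUT[ord("u")] = T

_BASES = np.frombuffer(b"ACGT-N", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Nucleotide string -> uint8 code array."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]


def decode(codes: np.ndarray) -> str:
    """uint8 code array -> nucleotide string."""
    return _BASES[codes].tobytes().decode("ascii")


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of an A/C/G/T code array (N maps to N)."""
    out = codes[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


def is_transition(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Boolean mask: differing A/C/G/T sites that are transitions."""
    return (a != b) & ((a ^ b) == 2)
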