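"""Nucleotide-sequence helpers shared across the pipeline.

Sequences are plain uppercase strings over {A,C,G,T,N}; numeric routines
encode them as int8 arrays with A,C,G,T -> 0,1,2,3 (N -> -1).
"""
from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_ENCODE = np.full(128, -1, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A,C,G,T -> 0..3; others -> -1)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


def revcomp_matrix(mat: np.ndarray) -> np.ndarray:
    """Reverse complement of a (width x 4) count/frequency matrix.

    Reverses the positions and swaps A<->T, C<->G, i.e. the matrix a
    palindromic motif model must equal.
    """
    return mat[::-1, ::-1]
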