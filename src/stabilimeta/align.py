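"""Pairwise identity for reference clustering.

Identity is defined as matches / alignment columns, gaps counting as
columns.  For equal-length ungapped references (the synthetic database uses
a fixed-length, indel-free substitution model) this reduces to positionwise
identity, which is exact and fast.  Unequal-length pairs fall back to a
global (Needleman-Wunsch) alignment.
"""

from __future__ import annotations

import numpy as np
from Bio import Align

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1.0
_aligner.mismatch_score = -1.0
_aligner.open_gap_score = -2.0
_aligner.extend_gap_score = -0.5


def pairwise_identity(a: str, b: str) -> float:
    """Fractional identity (0..1) of a global alignment of ``a`` and ``b``."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot align empty sequences")
    if len(a) == len(b):
        xa = np.frombuffer(a.encode(), dtype="S1")
        xb = np.frombuffer(b.encode(), dtype="S1")
        return float((xa == xb).sum()) / len(a)
    alignment = _aligner.align(a, b)[0]
    cols = alignment.length
    sa, sb = alignment[0], alignment[1]
    matches = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
    return matches / cols


def identity_matrix(sequences: list[str]) -> np.ndarray:
    """All-pairs identity matrix (diagonal 1.0)."""
    n = len(sequences)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pairwise_identity(sequences[i], sequences[j])
    return out
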