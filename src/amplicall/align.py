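"""Local sequence alignment.

Affine-gap Smith-Waterman used both for read-pair overlap detection and for
aligning merged reads against amplicon reference sequences.  The gap model
charges ``gap_open`` for the first base of a gap and ``gap_extend`` for each
subsequent base.  Tie-breaking is fully deterministic: among equal-scoring
alignments the one ending earliest in ``a`` wins, then earliest in ``b``,
then the traceback prefers diagonal moves (fewest gap openings) and closes
gaps as early as possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = ["AlignScores", "LocalAlignment", "smith_waterman"]

# op codes shared with the numba kernel
_OP_MATCH, _OP_MISMATCH, _OP_INS, _OP_DEL = 0, 1, 2, 3
_OP_CHARS = "=XID"


@dataclass(frozen=True)
class AlignScores:
    """Alignment scoring parameters (match > 0; penalties <= 0)."""

    match: int = 2
    mismatch: int = -2
    gap_open: int = -3
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("mismatch/gap penalties must be <= 0")


@dataclass(frozen=True)
class LocalAlignment:
    """Result of a local alignment of ``a`` against ``b``.

    Spans are 0-based half-open.  ``ops`` is a run-length encoded list of
    ``(op, length)`` with op one of ``"="`` (match), ``"X"`` (mismatch),
    ``"I"`` (bases present only in ``a``) and ``"D"`` (bases present only
    in ``b``).
    """

    score: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    ops: tuple[tuple[str, int], ...] = field(default=())

    @property
    def a_span(self) -> int:
        return self.a_end - self.a_start

    @property
    def b_span(self) -> int:
        return self.b_end - self.b_start

    def rescore(self, scores: AlignScores) -> int:
        """Recompute the score from the edit operations (consistency check)."""
        total = 0
        for op, length in self.ops:
            if op == "=":
                total += scores.match * length
            elif op == "X":
                total += scores.mismatch * length
            else:
                total += scores.gap_open + scores.gap_extend * (length - 1)
        return total


@njit(cache=True)
def _sw_kernel(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n = a.shape[0]
    m = b.shape[0]
    NEG = -(10**9)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in b (consumes a)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in a (consumes b)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i - 1, j] + gap_open, E[i - 1, j] + gap_extend)
            F[i, j] = max(H[i, j - 1] + gap_open, F[i, j - 1] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            h = H[i - 1, j - 1] + s
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:  # strict: keeps earliest (i, j) on ties
                best = h
                bi = i
                bj = j
    # traceback with explicit state; ops written reversed then flipped
    ops = np.empty(n + m, dtype=np.int8)
    k = 0
    i = bi
    j = bj
    state = 0  # 0=H, 1=E, 2=F
    while True:
        if state == 0:
            if H[i, j] == 0:
                break
            s = match if a[i - 1] == b[j - 1] else mismatch
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + s:
                ops[k] = _OP_MATCH if a[i - 1] == b[j - 1] else _OP_MISMATCH
                k += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[k] = _OP_INS
            k += 1
            if E[i, j] == H[i - 1, j] + gap_open:  # close the gap asap
                state = 0
            i -= 1
        else:
            ops[k] = _OP_DEL
            k += 1
            if F[i, j] == H[i, j - 1] + gap_open:
                state = 0
            j -= 1
    return best, i, bi, j, bj, ops[:k][::-1].copy()


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def smith_waterman(a: str, b: str, scores: AlignScores | None = None) -> LocalAlignment:
    """Best-scoring local alignment of ``a`` against ``b``.

    Returns an empty alignment (score 0, zero-length spans) when no cell of
    the dynamic-programming matrix is positive.
    """
    if not a or not b:
        raise ValueError("smith_waterman requires non-empty sequences")
    sc = scores or AlignScores()
    score, a0, a1, b0, b1, raw = _sw_kernel(
        _encode(a), _encode(b),
        np.int32(sc.match), np.int32(sc.mismatch),
        np.int32(sc.gap_open), np.int32(sc.gap_extend),
    )
    if score <= 0:
        return LocalAlignment(0, 0, 0, 0, 0, ())
    ops: list[tuple[str, int]] = []
    for code in raw:
        ch = _OP_CHARS[code]
        if ops and ops[-1][0] == ch:
            ops[-1] = (ch, ops[-1][1] + 1)
        else:
            ops.append((ch, 1))
    return LocalAlignment(int(score), int(a0), int(a1), int(b0), int(b1),
                          tuple(ops))
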