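"""Overlap-based consensus merging of amplicon read pairs.

Amplicon assays place the forward and reverse primers slightly further apart
than the sequencer read length, so the two mates of a pair overlap across the
region of interest.  Both mates derive from one DNA molecule, which lets the
overlap be collapsed into a single consensus read whose random sequencing
errors are reduced: agreeing bases gain quality, disagreeing bases are
resolved in favour of the higher-quality mate.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import AlignScores, smith_waterman

__all__ = [
    "ReadPair",
    "MergeParams",
    "MergedRead",
    "revcomp",
    "consensus_base",
    "merge_pair",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_ALPHABET = frozenset("ACGTN")

#: cap applied to the summed quality of two agreeing bases
MAX_CONSENSUS_QUAL = 60
#: quality assigned when two equal-quality bases disagree
TIE_QUAL = 2


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadPair:
    id: str
    seq1: str
    qual1: tuple[int, ...]
    seq2: str
    qual2: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")
        for seq in (self.seq1, self.seq2):
            if not set(seq) <= _ALPHABET:
                raise ValueError(f"read {self.id}: non-ACGTN base in sequence")


@dataclass(frozen=True)
class MergeParams:
    """Overlap-alignment parameters.

    ``min_overlap`` / ``min_overlap_identity`` reject spurious overlaps:
    pairs whose best local alignment is shorter than ``min_overlap`` bases
    or less than ``min_overlap_identity`` identical are left unmerged.
    """

    scores: AlignScores = AlignScores()
    min_overlap: int = 15
    min_overlap_identity: float = 0.90

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0.0 < self.min_overlap_identity <= 1.0:
            raise ValueError("min_overlap_identity must be in (0, 1]")


@dataclass(frozen=True)
class MergedRead:
    seq: str
    qual: tuple[int, ...]
    overlap_len: int
    source_id: str


def consensus_base(b1: str, q1: int, b2: str, q2: int) -> tuple[str, int]:
    """Consensus of one overlapping base pair.

    Agreement sums the qualities (capped at 60); disagreement keeps the
    higher-quality base at quality ``|q1 - q2|``; an exact quality tie keeps
    the read-1 base at quality 2.
    """
    if b1 == b2:
        return b1, min(q1 + q2, MAX_CONSENSUS_QUAL)
    if q1 > q2:
        return b1, q1 - q2
    if q2 > q1:
        return b2, q2 - q1
    return b1, TIE_QUAL


def merge_pair(pair: ReadPair, params: MergeParams | None = None) -> MergedRead | None:
    """Merge an overlapping read pair into a consensus read.

    Read 2 is reverse-complemented and locally aligned against read 1.  If
    the overlap passes the length and identity thresholds, the consensus
    spans the union of both reads: non-overlapping flanks are copied
    verbatim with their qualities, overlapping columns go through
    :func:`consensus_base`.  Returns ``None`` when the pair is unmergeable.
    """
    params = params or MergeParams()
    a = pair.seq1
    qa = pair.qual1
    b = revcomp(pair.seq2)
    qb = tuple(reversed(pair.qual2))
    aln = smith_waterman(a, b, params.scores)
    if aln.a_span < params.min_overlap:
        return None
    ncols = sum(length for _, length in aln.ops)
    nmatch = sum(length for op, length in aln.ops if op == "=")
    if ncols == 0 or nmatch / ncols < params.min_overlap_identity:
        return None

    seq: list[str] = []
    qual: list[int] = []
    # left flank from whichever read overhangs further
    if aln.a_start >= aln.b_start:
        seq.append(a[: aln.a_start])
        qual.extend(qa[: aln.a_start])
    else:
        seq.append(b[: aln.b_start])
        qual.extend(qb[: aln.b_start])
    i, j = aln.a_start, aln.b_start
    for op, length in aln.ops:
        for _ in range(length):
            if op in "=X":
                base, q = consensus_base(a[i], qa[i], b[j], qb[j])
                seq.append(base)
                qual.append(q)
                i += 1
                j += 1
            elif op == "I":  # base present only in read 1
                seq.append(a[i])
                qual.append(qa[i])
                i += 1
            else:  # "D": base present only in read 2
                seq.append(b[j])
                qual.append(qb[j])
                j += 1
    if len(a) - aln.a_end >= len(b) - aln.b_end:
        seq.append(a[aln.a_end:])
        qual.extend(qa[aln.a_end:])
    else:
        seq.append(b[aln.b_end:])
        qual.extend(qb[aln.b_end:])
    return MergedRead("".join(seq), tuple(qual), aln.a_span, pair.id)
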