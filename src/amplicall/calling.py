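"""Amplicon-anchored variant calling.

Each merged read pair is assigned to an amplicon by matching the start of
read 1 against the forward primer and the start of read 2 against the
reverse primer (Hamming distance, no alignment needed because primer
positions are known).  The merged consensus is then locally aligned against
the amplicon reference; mismatches and gaps in the alignment become raw
variants.  Variants on the same merged read that lie within a configurable
phasing window of each other originate from one DNA strand and are combined
into a compound in-phase (delins) parent while the individual constituents
are also reported.  Results per raw read pair are cached, so recurring
pairs skip merge/align/call entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pysam

from .align import AlignScores, smith_waterman
from .hgvs import GenomicVariant, trim_parsimonious
from .merge import MergedRead, MergeParams, ReadPair, merge_pair
from .panel import AmpliconDef, Panel

__all__ = [
    "CallingParams",
    "RawVariant",
    "PhasedGroup",
    "VariantCall",
    "RunStats",
    "CallSet",
    "assign_amplicon",
    "call_read",
    "phase",
    "process_sample",
    "evaluate",
]


@dataclass(frozen=True)
class CallingParams:
    """Thresholds and windows for calling.

    ``phase_window`` is the maximum number of reference bases between the
    end of one variant and the start of the next for the two to be phased
    into a compound delins.  Threshold comparisons are inclusive
    (``vaf >= min_vaf`` retains the call).
    """

    phase_window: int = 15
    min_vaf: float = 0.20
    min_alt_reads: int = 5
    primer_mismatch_max: int = 3
    min_read_fraction_aligned: float = 0.5
    scores: AlignScores = AlignScores()
    merge: MergeParams = MergeParams()

    def __post_init__(self) -> None:
        if self.phase_window < 0:
            raise ValueError("phase_window must be >= 0")
        if not 0.0 <= self.min_vaf <= 1.0:
            raise ValueError("min_vaf must be in [0, 1]")
        if self.min_alt_reads < 0:
            raise ValueError("min_alt_reads must be >= 0")


@dataclass(frozen=True, order=True)
class RawVariant:
    """One VCF-style variant observed on a merged read."""

    chrom: str
    pos: int  # 1-based genomic
    ref: str
    alt: str
    amplicon: str = field(compare=False, default="")

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref/alt must be non-empty (VCF anchored form)")
        if self.ref == self.alt:
            raise ValueError("ref == alt is not a variant")

    @property
    def end(self) -> int:
        return self.pos + len(self.ref) - 1

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def as_genomic(self) -> GenomicVariant:
        return GenomicVariant(self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class PhasedGroup:
    parent: RawVariant
    constituents: tuple[RawVariant, ...]

    def __post_init__(self) -> None:
        if len(self.constituents) < 2:
            raise ValueError("a phased group needs >= 2 constituents")

    @property
    def link(self) -> str:
        p = self.parent
        return f"{p.chrom}_{p.pos}_{p.ref}_{p.alt}"


@dataclass
class VariantCall:
    variant: RawVariant
    alt_pairs: int
    depth_pairs: int
    is_mnp_parent: bool = False
    mnp_link: str | None = None
    amplicons: tuple[str, ...] = ()
    filters: tuple[str, ...] = ()  # empty == PASS

    @property
    def vaf(self) -> float:
        return self.alt_pairs / self.depth_pairs if self.depth_pairs else 0.0


@dataclass
class RunStats:
    pairs_total: int = 0
    pairs_merged: int = 0
    pairs_assigned: int = 0
    pairs_unalignable: int = 0
    cache_hits: int = 0
    cache_misses: int = 0

    @property
    def cache_hit_ratio(self) -> float:
        n = self.cache_hits + self.cache_misses
        return self.cache_hits / n if n else 0.0


@dataclass
class CallSet:
    sample: str
    calls: list[VariantCall]
    stats: RunStats


# -- per-read operations ----------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def assign_amplicon(pair: ReadPair, panel: Panel,
                    params: CallingParams) -> AmpliconDef | None:
    """Match the read pair to an amplicon via its primer prefixes.

    Both primers must match the starts of their mates with at most
    ``primer_mismatch_max`` mismatches each; among several matching
    amplicons the lowest total mismatch count wins, an exact tie is
    unassigned.
    """
    best: AmpliconDef | None = None
    best_mm = None
    tie = False
    for amp in panel.amplicons:
        f, r = amp.fwd_primer, amp.rev_primer
        if len(pair.seq1) < len(f) or len(pair.seq2) < len(r):
            continue
        mm1 = _hamming(pair.seq1[:len(f)], f)
        if mm1 > params.primer_mismatch_max:
            continue
        mm2 = _hamming(pair.seq2[:len(r)], r)
        if mm2 > params.primer_mismatch_max:
            continue
        total = mm1 + mm2
        if best_mm is None or total < best_mm:
            best, best_mm, tie = amp, total, False
        elif total == best_mm:
            tie = True
    return None if tie else best


def call_read(merged: MergedRead, amplicon: AmpliconDef,
              params: CallingParams) -> tuple[list[RawVariant],
                                              tuple[int, int]] | None:
    """Extract raw variants from one merged read.

    Aligns the consensus against the amplicon reference and walks the edit
    operations: every mismatched base becomes a substitution, every gap run
    becomes one anchored indel.  Variants whose changed bases fall in a
    primer-binding region are dropped (primer bases are synthetic).
    Returns ``(variants, covered genomic interval)`` or None when the
    alignment covers less than half the merged read (unalignable).
    """
    aln = smith_waterman(merged.seq, amplicon.ref_seq, params.scores)
    if aln.a_span < params.min_read_fraction_aligned * len(merged.seq):
        return None
    variants: list[RawVariant] = []
    a, ref = merged.seq, amplicon.ref_seq
    g0 = amplicon.start  # genomic position of ref[0]
    i, j = aln.a_start, aln.b_start
    for op, length in aln.ops:
        if op == "=":
            i += length
            j += length
        elif op == "X":
            for k in range(length):
                variants.append(RawVariant(
                    amplicon.chrom, g0 + j + k, ref[j + k], a[i + k],
                    amplicon.name))
            i += length
            j += length
        elif op == "I":  # insertion relative to the reference
            if j > 0:
                anchor = ref[j - 1]
                variants.append(RawVariant(
                    amplicon.chrom, g0 + j - 1, anchor,
                    anchor + a[i:i + length], amplicon.name))
            i += length
        else:  # "D": deletion relative to the reference
            if j > 0:
                anchor = ref[j - 1]
                variants.append(RawVariant(
                    amplicon.chrom, g0 + j - 1,
                    anchor + ref[j:j + length], anchor, amplicon.name))
            j += length
    coverage = (g0 + aln.b_start, g0 + aln.b_end - 1)
    variants = [v for v in variants if not _in_primer(v, amplicon)]
    return variants, coverage


def _in_primer(v: RawVariant, amplicon: AmpliconDef) -> bool:
    """True when any changed base (or an insertion point) lies in a primer."""
    if len(v.ref) == 1 and len(v.alt) == 1:
        lo = hi = v.pos
    elif len(v.ref) > 1:  # deletion / delins: changed bases after the anchor
        lo, hi = v.pos + 1, v.end
    else:  # insertion between pos and pos+1
        lo, hi = v.pos, v.pos + 1
    fwd_end = amplicon.insert_start - 1
    rev_start = amplicon.insert_end + 1
    return lo <= fwd_end or hi >= rev_start


def phase(variants: list[RawVariant], amplicon: AmpliconDef,
          window: int) -> tuple[list[RawVariant], list[PhasedGroup]]:
    """Group per-read variants lying within ``window`` bases of each other.

    The gap is measured between the reference end of one variant and the
    reference start of the next and the relation is closed transitively.
    Each group of two or more yields a compound delins parent spanning the
    first to last changed reference base, built by applying the constituent
    edits to the amplicon reference; constituents are retained.
    """
    ordered = sorted(variants)
    groups: list[list[RawVariant]] = []
    for v in ordered:
        if groups and (v.pos - groups[-1][-1].end - 1) <= window:
            groups[-1].append(v)
        else:
            groups.append([v])
    phased: list[PhasedGroup] = []
    for grp in groups:
        if len(grp) < 2:
            continue
        parent = _build_parent(grp, amplicon)
        phased.append(PhasedGroup(parent, tuple(grp)))
    return ordered, phased


def _changed_span(v: RawVariant) -> tuple[int, int, str]:
    """(first changed pos, last changed pos, replacement) with VCF anchors
    stripped; insertions get a zero-length reference span."""
    if len(v.ref) == 1 and len(v.alt) == 1:
        return v.pos, v.pos, v.alt
    if len(v.ref) > 1 and v.alt == v.ref[0]:  # deletion
        return v.pos + 1, v.end, ""
    if len(v.alt) > 1 and v.ref == v.alt[0]:  # insertion
        return v.pos + 1, v.pos, v.alt[1:]
    return v.pos, v.end, v.alt  # general delins


def _build_parent(grp: list[RawVariant], amplicon: AmpliconDef) -> RawVariant:
    span_start = min(v.pos for v in grp)
    span_end = max(v.end for v in grp)
    ref = amplicon.ref_seq[span_start - amplicon.start:
                           span_end - amplicon.start + 1]
    pieces: list[str] = []
    cursor = span_start
    for v in grp:
        s, e, repl = _changed_span(v)
        if s > cursor:
            pieces.append(amplicon.ref_seq[cursor - amplicon.start:
                                           s - amplicon.start])
        pieces.append(repl)
        cursor = max(cursor, e + 1)
    if cursor <= span_end:
        pieces.append(amplicon.ref_seq[cursor - amplicon.start:
                                       span_end - amplicon.start + 1])
    alt = "".join(pieces)
    return RawVariant(amplicon.chrom, span_start, ref, alt, amplicon.name)


# -- sample-level processing ------------------------------------------------

@dataclass
class _CacheEntry:
    amplicon: str | None
    assigned: bool
    merged: bool
    alignable: bool
    coverage: tuple[str, int, int] | None
    variants: tuple[RawVariant, ...]
    parents: tuple[PhasedGroup, ...]


def _process_pair(pair: ReadPair, panel: Panel,
                  params: CallingParams) -> _CacheEntry:
    amp = assign_amplicon(pair, panel, params)
    if amp is None:
        return _CacheEntry(None, False, False, False, None, (), ())
    merged = merge_pair(pair, params.merge)
    if merged is None:
        return _CacheEntry(amp.name, True, False, False, None, (), ())
    called = call_read(merged, amp, params)
    if called is None:
        return _CacheEntry(amp.name, True, True, False, None, (), ())
    variants, (cov_s, cov_e) = called
    singles, groups = phase(variants, amp, params.phase_window)
    return _CacheEntry(amp.name, True, True, True, (amp.chrom, cov_s, cov_e),
                       tuple(singles), tuple(groups))


def iter_fastq_pairs(fastq1: str | Path, fastq2: str | Path):
    """Yield ReadPair objects from two (optionally gzipped) FASTQ files."""
    with pysam.FastxFile(str(fastq1)) as f1, pysam.FastxFile(str(fastq2)) as f2:
        it1, it2 = iter(f1), iter(f2)
        while True:
            r1 = next(it1, None)
            r2 = next(it2, None)
            if r1 is None and r2 is None:
                return
            if r1 is None or r2 is None:
                raise ValueError(
                    f"mate-count mismatch between {fastq1} and {fastq2}")
            yield ReadPair(r1.name, r1.sequence.upper(),
                           tuple(r1.get_quality_array()),
                           r2.sequence.upper(),
                           tuple(r2.get_quality_array()))


def process_sample(fastq1: str | Path, fastq2: str | Path, panel: Panel,
                   params: CallingParams | None = None,
                   cache_enabled: bool = True, sample: str | None = None,
                   emit_all: bool = False) -> CallSet:
    """Run merge → assign → call → phase over a FASTQ pair and aggregate.

    Per-variant support (``alt_pairs``) counts merged pairs exhibiting the
    variant; depth (``depth_pairs``) counts merged, assigned pairs whose
    alignment covers the variant's reference span, summed across amplicons
    when a locus is tiled by several.  Calls failing ``min_vaf`` /
    ``min_alt_reads`` are dropped unless ``emit_all`` is set, in which case
    they carry LowVAF/LowDepth filters.
    """
    params = params or CallingParams()
    sample = sample or Path(str(fastq1)).name.split(".")[0]
    stats = RunStats()
    cache: dict[tuple[str, str], _CacheEntry] = {}

    alt_counts: dict[tuple, int] = {}
    meta: dict[tuple, RawVariant] = {}
    parent_links: dict[tuple, str] = {}
    parent_keys: set[tuple] = set()
    amps_of: dict[tuple, set[str]] = {}
    coverages: dict[tuple[str, int, int], int] = {}

    def account(entry: _CacheEntry) -> None:
        if entry.assigned:
            stats.pairs_assigned += 1
        if entry.merged:
            stats.pairs_merged += 1
            if not entry.alignable:
                stats.pairs_unalignable += 1
        if entry.coverage is not None:
            coverages[entry.coverage] = coverages.get(entry.coverage, 0) + 1
        seen: set[tuple] = set()
        for v in entry.variants:
            k = v.key()
            if k in seen:
                continue
            seen.add(k)
            alt_counts[k] = alt_counts.get(k, 0) + 1
            meta.setdefault(k, v)
            amps_of.setdefault(k, set()).add(v.amplicon)
        for grp in entry.parents:
            k = grp.parent.key()
            if k not in seen:
                seen.add(k)
                alt_counts[k] = alt_counts.get(k, 0) + 1
                meta.setdefault(k, grp.parent)
                amps_of.setdefault(k, set()).add(grp.parent.amplicon)
            parent_keys.add(k)
            parent_links.setdefault(k, grp.link)
            for c in grp.constituents:
                parent_links.setdefault(c.key(), grp.link)

    for pair in iter_fastq_pairs(fastq1, fastq2):
        stats.pairs_total += 1
        key = (pair.seq1, pair.seq2)
        if cache_enabled and key in cache:
            stats.cache_hits += 1
            account(cache[key])
            continue
        stats.cache_misses += 1
        entry = _process_pair(pair, panel, params)
        if cache_enabled:
            cache[key] = entry
        account(entry)

    calls: list[VariantCall] = []
    for k, alt in alt_counts.items():
        v = meta[k]
        depth = sum(n for (chrom, s, e), n in coverages.items()
                    if chrom == v.chrom and s <= v.pos and v.end <= e)
        call = VariantCall(
            variant=v, alt_pairs=alt, depth_pairs=depth,
            is_mnp_parent=k in parent_keys,
            mnp_link=parent_links.get(k),
            amplicons=tuple(sorted(amps_of[k])))
        filters = []
        if call.vaf < params.min_vaf:
            filters.append("LowVAF")
        if call.alt_pairs < params.min_alt_reads:
            filters.append("LowDepth")
        if filters and not emit_all:
            continue
        call.filters = tuple(filters)
        calls.append(call)
    calls.sort(key=lambda c: c.variant.key())
    return CallSet(sample, calls, stats)


# -- evaluation -------------------------------------------------------------

def evaluate(callset: CallSet, truth: list[RawVariant]) -> dict:
    """Compare calls against a truth set on parsimonious-trimmed tuples."""

    def canon(v: RawVariant) -> tuple:
        return trim_parsimonious(v.as_genomic()).key()

    called = {canon(c.variant) for c in callset.calls}
    expected = {canon(v) for v in truth}
    tp = len(called & expected)
    fp = len(called - expected)
    fn = len(expected - called)
    return {
        "TP": tp, "FP": fp, "FN": fn,
        "sensitivity": tp / (tp + fn) if expected else None,
        "precision": tp / (tp + fp) if called else None,
    }
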