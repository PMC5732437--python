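"""Synthetic panels, transcripts and reads with planted variants.

Everything the pipeline needs for end-to-end runs can be generated here
without any reference downloads: random amplicon panels with
Hamming-separated primers, consistent toy transcript models (including a
BRAF-like gene whose codon 600 is GTG at c.1798-1800), and paired FASTQ
files in which variants are planted at chosen allele fractions together
with a truth table.

Simulated base qualities follow a deterministic declining profile across
the read (read 2 slightly worse than read 1), emulating real paired-end
behaviour.  Because qualities are a pure function of cycle, identical
sequence pairs always carry identical qualities, which keeps the
read-pair cache exactly equivalent to uncached processing.  Sequencing
errors are never injected into primer cycles, so amplicon assignment stays
unambiguous (a documented idealization).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .calling import RawVariant
from .hgvs import trim_parsimonious
from .merge import ReadPair, revcomp
from .panel import (AmpliconDef, Panel, PreferredTranscriptMap,
                    TranscriptModel, write_panel, write_preferred,
                    write_transcripts)

__all__ = [
    "SimSampleSpec",
    "make_panel",
    "make_braf_like_panel",
    "make_toy_coding_panel",
    "simulate_pairs",
    "write_sample",
    "quality_profile",
]

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + stop-free random codons + TAA (premature stops would truncate
    protein-consequence comparisons)."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_seq(rng, 3)
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def quality_profile(read_len: int, mate: int) -> tuple[int, ...]:
    """Deterministic per-cycle Phred profile: read 1 declines 38→28,
    read 2 declines 36→26."""
    top = 38 if mate == 1 else 36
    if read_len == 1:
        return (top,)
    return tuple(round(top - 10 * i / (read_len - 1)) for i in range(read_len))


# -- panel generation -------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def make_panel(n_amplicons: int = 8, insert_len: int = 200,
               primer_len: int = 20, seed: int = 0, chrom: str = "chrS",
               min_primer_distance: int = 7,
               max_tries: int = 500) -> Panel:
    """Random panel with pairwise Hamming-separated primers.

    All primers (forward and reverse, across amplicons) are at least
    ``min_primer_distance`` mismatches apart, which keeps primer-based
    amplicon assignment unambiguous up to the default mismatch tolerance.
    Amplicons are laid out on one synthetic chromosome, 500 bp apart.
    """
    if n_amplicons < 1 or insert_len < 1 or primer_len < 1:
        raise ValueError("panel dimensions must be positive")
    rng = np.random.default_rng(seed)
    primers: list[str] = []
    for _ in range(2 * n_amplicons):
        for attempt in range(max_tries):
            cand = _random_seq(rng, primer_len)
            if all(_hamming(cand, p) >= min_primer_distance for p in primers):
                primers.append(cand)
                break
        else:
            raise RuntimeError("could not generate Hamming-separated primers")
    amplicons = []
    total_len = insert_len + 2 * primer_len
    pos = 10001
    for i in range(n_amplicons):
        fwd, rev = primers[2 * i], primers[2 * i + 1]
        insert = _random_seq(rng, insert_len)
        ref = fwd + insert + revcomp(rev)
        amplicons.append(AmpliconDef(
            name=f"AMP{i + 1:03d}", chrom=chrom, start=pos,
            end=pos + total_len - 1, fwd_primer=fwd, rev_primer=rev,
            ref_seq=ref))
        pos += total_len + 500
    return Panel(tuple(amplicons))


def make_braf_like_panel(seed: int = 7) -> tuple[Panel, dict]:
    """Synthetic single-amplicon panel with a BRAF-like transcript.

    The (entirely synthetic) plus-strand transcript has two exons, a 100 bp
    5' UTR and a 650-codon CDS whose codon 600 is GTG, i.e. c.1798-1800
    encode valine exactly as in the classic kinase hot spot.  The amplicon
    covers the region of exon 2 containing codon 600.  Returns the panel
    and an info dict with the genomic coordinates of codon 600.
    """
    rng = np.random.default_rng(seed)
    utr5 = _random_seq(rng, 100)
    cds = list(_random_cds(rng, 650))
    cds[3 * 599:3 * 600] = "GTG"  # codon 600
    cds = "".join(cds)
    utr3 = _random_seq(rng, 150)
    spliced = utr5 + cds + utr3  # 2200 bp
    tx = TranscriptModel(
        accession="NM_900001.1", gene="BRAF", chrom="chrB", strand="+",
        exons=((1001, 2800), (5041, 5440)),
        cds_start_c=101, cds_end_c=2050, spliced_seq=spliced)
    # amplicon chrB:5001-5240 covering genomic 5041-5220 of exon 2
    fwd = _random_seq(rng, 20)
    rev = _random_seq(rng, 20)
    intron_tail = _random_seq(rng, 20)        # genomic 5021-5040
    exonic = spliced[1800:1980]               # genomic 5041-5220
    ref = fwd + intron_tail + exonic + revcomp(rev)
    amp = AmpliconDef(name="BRAF_600", chrom="chrB", start=5001, end=5240,
                      fwd_primer=fwd, rev_primer=rev, ref_seq=ref)
    panel = Panel((amp,), (tx,),
                  PreferredTranscriptMap({"BRAF": tx.accession}))
    info = {
        "amplicon": amp.name,
        "c1798_g": 5138,  # spliced 1898 = exon2 offset 98 -> 5041 + 97
        "codon600_g": (5138, 5139, 5140),
        "codon600": "GTG",
    }
    assert exonic[97:100] == "GTG"
    return panel, info


def make_toy_coding_panel(seed: int = 0, strand: str = "+",
                          cds_seq: str | None = None, n_codons: int = 30,
                          utr5: int = 12, utr3: int = 12, pad: int = 10,
                          primer_len: int = 15, gene: str = "TOY1",
                          accession: str = "NM_910001.1",
                          chrom: str = "chrT") -> tuple[Panel, dict]:
    """One amplicon containing a complete single-exon toy transcript.

    ``cds_seq`` lets tests control the coding sequence (e.g. to place a
    repeat for duplication calls); by default a random stop-free CDS of
    ``n_codons`` codons is generated.  ``strand`` may be '-' to exercise
    minus-strand coordinate mapping and 3' shifting.
    """
    rng = np.random.default_rng(seed)
    if cds_seq is None:
        cds_seq = _random_cds(rng, n_codons)
    if len(cds_seq) % 3:
        raise ValueError("cds_seq length must be a multiple of 3")
    spliced = _random_seq(rng, utr5) + cds_seq + _random_seq(rng, utr3)
    exon_len = len(spliced)
    start = 2001
    exon_g = (start + primer_len + pad,
              start + primer_len + pad + exon_len - 1)
    tx = TranscriptModel(
        accession=accession, gene=gene, chrom=chrom, strand=strand,
        exons=(exon_g,),
        cds_start_c=utr5 + 1, cds_end_c=utr5 + len(cds_seq),
        spliced_seq=spliced)
    genomic_exon = spliced if strand == "+" else revcomp(spliced)
    fwd = _random_seq(rng, primer_len)
    rev = _random_seq(rng, primer_len)
    insert = _random_seq(rng, pad) + genomic_exon + _random_seq(rng, pad)
    ref = fwd + insert + revcomp(rev)
    amp = AmpliconDef(name=f"{gene}_A1", chrom=chrom, start=start,
                      end=start + len(ref) - 1, fwd_primer=fwd,
                      rev_primer=rev, ref_seq=ref)
    panel = Panel((amp,), (tx,), PreferredTranscriptMap({gene: accession}))
    info = {"exon_g": exon_g, "amplicon": amp.name}
    return panel, info


# -- read simulation --------------------------------------------------------

@dataclass(frozen=True)
class SimSampleSpec:
    """Study conditions for one simulated sample.

    ``planted`` pairs each variant with its target allele fraction; per
    amplicon the fractions must leave room for the reference haplotype.
    ``error_rate`` is the per-base substitution probability outside primer
    cycles.
    """

    panel: Panel
    planted: tuple[tuple[RawVariant, float], ...] = ()
    depth: int = 2000
    read_len: int = 150
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        by_amp: dict[str, float] = {}
        amps = {a.name: a for a in self.panel.amplicons}
        for v, f in self.planted:
            if not 0.0 <= f <= 1.0:
                raise ValueError("planted fraction must be in [0, 1]")
            amp = amps.get(v.amplicon)
            if amp is None:
                raise ValueError(f"planted variant names unknown amplicon "
                                 f"{v.amplicon}")
            if not (amp.insert_start <= v.pos and v.end <= amp.insert_end):
                raise ValueError(
                    f"planted variant at {v.chrom}:{v.pos} outside the "
                    f"insert of {amp.name}")
            by_amp[amp.name] = by_amp.get(amp.name, 0.0) + f
        if any(f > 1.0 + 1e-9 for f in by_amp.values()):
            raise ValueError("planted fractions exceed 1 within an amplicon")
        for a in self.panel.amplicons:
            if self.read_len < len(a.fwd_primer) + 15:
                raise ValueError("read_len too short for primer + overlap")
            if len(a.ref_seq) >= 2 * self.read_len:
                raise ValueError(
                    f"amplicon {a.name} too long for overlapping "
                    f"{self.read_len} bp reads")


def _apply_variant(amp: AmpliconDef, v: RawVariant) -> str:
    off = v.pos - amp.start
    if amp.ref_seq[off:off + len(v.ref)] != v.ref:
        raise ValueError(f"planted ref allele mismatch at {v.chrom}:{v.pos}")
    return amp.ref_seq[:off] + v.alt + amp.ref_seq[off + len(v.ref):]


def simulate_pairs(spec: SimSampleSpec, mode: str = "binomial"
                   ) -> tuple[list[ReadPair], list[tuple[RawVariant, int]]]:
    """Draw read pairs per amplicon and report realized alt-pair counts.

    ``exact`` mode assigns round(fraction x depth) pairs per variant
    haplotype deterministically; ``binomial`` samples each pair's haplotype
    independently.  The truth table lists each planted variant in its
    parsimonious-trimmed form with the number of pairs actually drawn from
    its haplotype.
    """
    if mode not in ("binomial", "exact"):
        raise ValueError("mode must be 'binomial' or 'exact'")
    rng = np.random.default_rng(spec.seed)
    pairs: list[ReadPair] = []
    truth: list[tuple[RawVariant, int]] = []
    for amp in spec.panel.amplicons:
        planted = [(v, f) for v, f in spec.planted if v.amplicon == amp.name]
        haplos = [_apply_variant(amp, v) for v, _ in planted]
        fracs = [f for _, f in planted]
        if mode == "exact":
            counts = [int(np.floor(f * spec.depth + 0.5)) for f in fracs]
        else:
            probs = fracs + [max(0.0, 1.0 - sum(fracs))]
            counts = list(rng.multinomial(spec.depth, np.array(probs) /
                                          sum(probs)))[:len(fracs)]
        counts = [min(c, spec.depth) for c in counts]
        n_ref = spec.depth - sum(counts)
        plan = [(amp.ref_seq, n_ref)] + [
            (h, c) for h, c in zip(haplos, counts)]
        idx = 0
        primer_len = len(amp.fwd_primer)
        for frag, n in plan:
            rl = min(spec.read_len, len(frag))
            q1 = quality_profile(rl, 1)
            q2 = quality_profile(rl, 2)
            for _ in range(n):
                s1 = _sequence_read(frag[:rl], primer_len,
                                    spec.error_rate, rng)
                s2 = _sequence_read(revcomp(frag)[:rl], primer_len,
                                    spec.error_rate, rng)
                pairs.append(ReadPair(f"{amp.name}:{idx}", s1, q1, s2, q2))
                idx += 1
        for (v, _), c in zip(planted, counts):
            g = trim_parsimonious(v.as_genomic())
            truth.append((RawVariant(g.chrom, g.pos, g.ref, g.alt,
                                     amp.name), c))
    return pairs, truth


def _sequence_read(template: str, primer_len: int, error_rate: float,
                   rng: np.random.Generator) -> str:
    if error_rate == 0.0:
        return template
    bases = list(template)
    hits = np.nonzero(rng.random(len(bases)) < error_rate)[0]
    for i in hits:
        if i < primer_len:
            continue  # primer cycles stay error-free
        choices = [b for b in _BASES if b != bases[i]]
        bases[i] = choices[rng.integers(0, 3)]
    return "".join(bases)


# -- file output ------------------------------------------------------------

def write_sample(spec: SimSampleSpec, out_dir: str | Path,
                 mode: str = "binomial", prefix: str = "sim") -> dict:
    """Write gzipped FASTQ pair, panel files, transcripts, preferred map and
    truth TSV; returns a dict of the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pairs, truth = simulate_pairs(spec, mode)
    paths = {
        "fastq1": out / f"{prefix}_R1.fastq.gz",
        "fastq2": out / f"{prefix}_R2.fastq.gz",
        "manifest": out / f"{prefix}_panel.tsv",
        "fasta": out / f"{prefix}_panel.fasta",
        "transcripts": out / f"{prefix}_transcripts.json",
        "preferred": out / f"{prefix}_preferred.tsv",
        "truth": out / f"{prefix}_truth.tsv",
    }
    for key, mate in (("fastq1", 1), ("fastq2", 2)):
        with gzip.open(paths[key], "wt") as fh:
            for p in pairs:
                seq = p.seq1 if mate == 1 else p.seq2
                qual = p.qual1 if mate == 1 else p.qual2
                fh.write(f"@{p.id}\n{seq}\n+\n"
                         + "".join(chr(q + 33) for q in qual) + "\n")
    write_panel(spec.panel, paths["manifest"], paths["fasta"])
    write_transcripts(spec.panel.transcripts, paths["transcripts"])
    write_preferred(spec.panel.preferred, paths["preferred"])
    with open(paths["truth"], "w") as fh:
        fh.write("chrom\tpos\tref\talt\tamplicon\talt_pairs\tdepth\n")
        for v, c in truth:
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.amplicon}\t"
                     f"{c}\t{spec.depth}\n")
    return paths
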