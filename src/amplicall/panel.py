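"""Amplicon panel, transcript models and preferred-transcript map.

The panel manifest is a TSV with header columns exactly
``name, chrom, start, end, fwd_primer, rev_primer`` (coordinates 1-based
inclusive, spanning the full amplicon including both primers).  Per-amplicon
reference sequences are supplied as a FASTA whose record ids equal the
manifest names.  Transcript models are a JSON document (list of objects with
keys ``accession, gene, chrom, strand, exons, cds_start_c, cds_end_c,
spliced_seq``); the preferred-transcript map is a two-column TSV
(gene, accession).

Primers are given as sequenced: ``fwd_primer`` on the forward genomic
strand (start of read 1), ``rev_primer`` on the reverse strand (start of
read 2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .merge import revcomp

__all__ = [
    "PanelError",
    "AmpliconDef",
    "TranscriptModel",
    "PreferredTranscriptMap",
    "Panel",
    "ReferenceIndex",
    "load_panel",
    "load_transcripts",
    "load_preferred",
    "write_panel",
    "write_transcripts",
    "write_preferred",
]


class PanelError(ValueError):
    """Raised when a panel/transcript input fails validation."""


@dataclass(frozen=True)
class AmpliconDef:
    """One amplicon: primers, genomic interval and full reference insert."""

    name: str
    chrom: str
    start: int  # 1-based inclusive, includes fwd primer
    end: int    # 1-based inclusive, includes rev primer
    fwd_primer: str
    rev_primer: str  # as sequenced (reverse strand)
    ref_seq: str     # forward genomic strand, full amplicon

    def __post_init__(self) -> None:
        if not self.fwd_primer or not self.rev_primer:
            raise PanelError(f"amplicon {self.name}: empty primer")
        if self.start > self.end:
            raise PanelError(f"amplicon {self.name}: start > end")
        if len(self.ref_seq) != self.end - self.start + 1:
            raise PanelError(
                f"amplicon {self.name}: ref_seq length {len(self.ref_seq)} != "
                f"interval length {self.end - self.start + 1}")
        if not self.ref_seq.startswith(self.fwd_primer):
            raise PanelError(
                f"amplicon {self.name}: ref_seq does not start with fwd_primer")
        if not self.ref_seq.endswith(revcomp(self.rev_primer)):
            raise PanelError(
                f"amplicon {self.name}: ref_seq does not end with "
                f"revcomp(rev_primer)")
        if self.insert_len <= 0:
            raise PanelError(f"amplicon {self.name}: zero-length insert")

    @property
    def insert_len(self) -> int:
        return len(self.ref_seq) - len(self.fwd_primer) - len(self.rev_primer)

    @property
    def insert_start(self) -> int:
        """Genomic start of the insert (first base after the fwd primer)."""
        return self.start + len(self.fwd_primer)

    @property
    def insert_end(self) -> int:
        """Genomic end of the insert (last base before the rev primer)."""
        return self.end - len(self.rev_primer)


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS geometry and spliced sequence of one transcript.

    ``exons`` are genomic intervals (1-based inclusive) sorted by genomic
    position regardless of strand; ``cds_start_c``/``cds_end_c`` are CDS
    bounds in transcript (spliced) coordinates; ``spliced_seq`` is on the
    transcript strand.
    """

    accession: str
    gene: str
    chrom: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]
    cds_start_c: int
    cds_end_c: int
    spliced_seq: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise PanelError(f"{self.accession}: strand must be '+' or '-'")
        prev_end = 0
        for s, e in self.exons:
            if s > e or s <= prev_end:
                raise PanelError(
                    f"{self.accession}: exons must be sorted and non-overlapping")
            prev_end = e
        total = sum(e - s + 1 for s, e in self.exons)
        if total != len(self.spliced_seq):
            raise PanelError(
                f"{self.accession}: exon lengths sum to {total} but "
                f"spliced_seq has {len(self.spliced_seq)} bases")
        if not 1 <= self.cds_start_c < self.cds_end_c <= len(self.spliced_seq):
            raise PanelError(f"{self.accession}: CDS bounds out of range")
        if (self.cds_end_c - self.cds_start_c + 1) % 3 != 0:
            raise PanelError(f"{self.accession}: CDS length not divisible by 3")

    # -- coordinate helpers -------------------------------------------------

    @property
    def g_start(self) -> int:
        return self.exons[0][0]

    @property
    def g_end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_seq(self) -> str:
        return self.spliced_seq[self.cds_start_c - 1:self.cds_end_c]

    def overlaps(self, chrom: str, start: int, end: int, flank: int = 0) -> bool:
        return (chrom == self.chrom and start <= self.g_end + flank
                and end >= self.g_start - flank)

    def _exon_tx_start(self, idx: int) -> int:
        """Transcript coordinate of the transcript-first base of exon idx."""
        if self.strand == "+":
            return 1 + sum(e - s + 1 for s, e in self.exons[:idx])
        return 1 + sum(e - s + 1 for s, e in self.exons[idx + 1:])

    def genomic_to_tx(self, gpos: int) -> tuple[int, int]:
        """Map a genomic position to (transcript position, intronic offset).

        Exonic positions return offset 0.  Intronic positions anchor to the
        nearest exonic base in genomic distance and carry a signed offset in
        transcript direction (+k past an exon end, -k before an exon start).
        Positions outside the transcript span anchor to the terminal exon
        base the same way.
        """
        for idx, (s, e) in enumerate(self.exons):
            if s <= gpos <= e:
                t0 = self._exon_tx_start(idx)
                if self.strand == "+":
                    return t0 + (gpos - s), 0
                return t0 + (e - gpos), 0
        # collect exon boundary anchors: (genomic distance, tx pos, direction)
        candidates: list[tuple[int, int, int]] = []
        for idx, (s, e) in enumerate(self.exons):
            t0 = self._exon_tx_start(idx)
            if self.strand == "+":
                tx_s, tx_e = t0, t0 + (e - s)
            else:
                tx_s, tx_e = t0 + (e - s), t0
            if gpos < s:
                # genomically before the exon start
                off = s - gpos
                sign = -1 if self.strand == "+" else +1
                candidates.append((off, tx_s, sign * off))
            elif gpos > e:
                off = gpos - e
                sign = +1 if self.strand == "+" else -1
                candidates.append((off, tx_e, sign * off))
        dist, tx, off = min(candidates)
        return tx, off

    def exon_distance(self, gpos: int) -> int:
        """Genomic distance from gpos to the nearest exon (0 if exonic)."""
        best = None
        for s, e in self.exons:
            if s <= gpos <= e:
                return 0
            d = s - gpos if gpos < s else gpos - e
            best = d if best is None else min(best, d)
        return best


@dataclass(frozen=True)
class PreferredTranscriptMap:
    mapping: dict[str, str] = field(default_factory=dict)

    def get(self, gene: str) -> str | None:
        return self.mapping.get(gene)

    def accessions(self) -> set[str]:
        return set(self.mapping.values())

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass(frozen=True)
class Panel:
    amplicons: tuple[AmpliconDef, ...]
    transcripts: tuple[TranscriptModel, ...] = ()
    preferred: PreferredTranscriptMap = field(default_factory=PreferredTranscriptMap)

    def __post_init__(self) -> None:
        names = [a.name for a in self.amplicons]
        if len(names) != len(set(names)):
            raise PanelError("duplicate amplicon names in panel")
        accs = {t.accession for t in self.transcripts}
        for gene, acc in self.preferred.mapping.items():
            if acc not in accs:
                raise PanelError(
                    f"preferred transcript {acc} for {gene} not in transcript set")

    def transcript(self, accession: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.accession == accession:
                return t
        raise KeyError(accession)

    def reference(self) -> "ReferenceIndex":
        return ReferenceIndex(self.amplicons)


class ReferenceIndex:
    """Genomic reference accessor backed by the panel's amplicon sequences."""

    def __init__(self, amplicons: tuple[AmpliconDef, ...]):
        self._by_chrom: dict[str, list[AmpliconDef]] = {}
        for a in amplicons:
            self._by_chrom.setdefault(a.chrom, []).append(a)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda a: a.start)

    def fetch(self, chrom: str, start: int, end: int) -> str | None:
        """Reference bases [start, end] (1-based inclusive) or None if the
        span is not fully contained in any single amplicon."""
        if start > end:
            return ""
        for a in self._by_chrom.get(chrom, ()):
            if a.start <= start and end <= a.end:
                return a.ref_seq[start - a.start:end - a.start + 1]
        return None

    def base(self, chrom: str, pos: int) -> str | None:
        seq = self.fetch(chrom, pos, pos)
        return seq or None


# -- loading / serialization ------------------------------------------------

_MANIFEST_COLS = ["name", "chrom", "start", "end", "fwd_primer", "rev_primer"]


def load_panel(manifest_path: str | Path, fasta_path: str | Path) -> Panel:
    """Load and validate an amplicon panel from manifest TSV + FASTA."""
    seqs = {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(fasta_path), "fasta")}
    amplicons = []
    with open(manifest_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _MANIFEST_COLS:
            raise PanelError(
                f"manifest header must be {_MANIFEST_COLS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_MANIFEST_COLS):
                raise PanelError(f"manifest line {lineno}: wrong column count")
            name, chrom, start, end, fwd, rev = fields
            if name not in seqs:
                raise PanelError(f"no FASTA record for amplicon {name}")
            amplicons.append(AmpliconDef(
                name=name, chrom=chrom, start=int(start), end=int(end),
                fwd_primer=fwd.upper(), rev_primer=rev.upper(),
                ref_seq=seqs[name]))
    return Panel(tuple(amplicons))


def load_transcripts(path: str | Path) -> tuple[TranscriptModel, ...]:
    with open(path) as fh:
        records = json.load(fh)
    out: list[TranscriptModel] = []
    seen: set[str] = set()
    for rec in records:
        tx = TranscriptModel(
            accession=rec["accession"], gene=rec["gene"], chrom=rec["chrom"],
            strand=rec["strand"],
            exons=tuple((int(s), int(e)) for s, e in rec["exons"]),
            cds_start_c=int(rec["cds_start_c"]), cds_end_c=int(rec["cds_end_c"]),
            spliced_seq=rec["spliced_seq"].upper())
        if tx.accession in seen:
            raise PanelError(f"duplicate transcript accession {tx.accession}")
        seen.add(tx.accession)
        out.append(tx)
    return tuple(out)


def load_preferred(path: str | Path,
                   transcripts: tuple[TranscriptModel, ...]) -> PreferredTranscriptMap:
    accs = {t.accession for t in transcripts}
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise PanelError(f"preferred map line {lineno}: expected 2 columns")
            gene, acc = fields
            if gene in mapping:
                raise PanelError(f"duplicate preferred-transcript row for {gene}")
            if acc not in accs:
                raise PanelError(
                    f"preferred transcript {acc} for {gene} not in transcript set")
            mapping[gene] = acc
    return PreferredTranscriptMap(mapping)


def write_panel(panel: Panel, manifest_path: str | Path,
                fasta_path: str | Path) -> None:
    with open(manifest_path, "w") as fh:
        fh.write("\t".join(_MANIFEST_COLS) + "\n")
        for a in panel.amplicons:
            fh.write(f"{a.name}\t{a.chrom}\t{a.start}\t{a.end}\t"
                     f"{a.fwd_primer}\t{a.rev_primer}\n")
    with open(fasta_path, "w") as fh:
        for a in panel.amplicons:
            fh.write(f">{a.name}\n{a.ref_seq}\n")


def write_transcripts(transcripts: tuple[TranscriptModel, ...],
                      path: str | Path) -> None:
    records = [{
        "accession": t.accession, "gene": t.gene, "chrom": t.chrom,
        "strand": t.strand, "exons": [list(ex) for ex in t.exons],
        "cds_start_c": t.cds_start_c, "cds_end_c": t.cds_end_c,
        "spliced_seq": t.spliced_seq,
    } for t in transcripts]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)
        fh.write("\n")


def write_preferred(preferred: PreferredTranscriptMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(preferred.mapping):
            fh.write(f"{gene}\t{preferred.mapping[gene]}\n")
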