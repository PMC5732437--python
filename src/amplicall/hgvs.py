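"""Variant normalization and HGVS nomenclature rendering.

VCF-style ``(chrom, pos, ref, alt)`` tuples are ambiguous: the same physical
edit can be written with different paddings and, inside repeats, at different
positions.  For clinical reporting every variant is reduced to a single
canonical form: shared ref/alt bases are trimmed away (parsimony), pure
indels are shifted as far 3' as possible *in the reading direction of the
selected transcript*, and insertions that copy the immediately preceding
sequence are re-classified as duplications.  The canonical edit is then
rendered as an (accession, HGVSg, HGVSc, HGVSp) triple.

By convention the genomic (g.) coordinate mirrors the transcript-shifted
position even for minus-strand transcripts, so the genomic position always
matches the cDNA position; intergenic variants fall back to a plus-strand
3' shift and carry HGVSg only.

The engine is local and offline.  Any component conforming to the same
operation signatures (e.g. a client for a remote normalization service)
can be substituted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Seq import Seq

from .panel import PreferredTranscriptMap, ReferenceIndex, TranscriptModel

__all__ = [
    "HgvsError",
    "GenomicVariant",
    "HgvsTriple",
    "NormalizedVariant",
    "trim_parsimonious",
    "shift_3prime",
    "classify_dup",
    "select_transcript",
    "to_hgvs",
    "predict_protein",
    "normalize",
]


class HgvsError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class GenomicVariant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref and not self.alt:
            raise HgvsError("ref and alt cannot both be empty")

    @property
    def end(self) -> int:
        """Last reference base of the (VCF-padded) ref allele."""
        return self.pos + len(self.ref) - 1

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class HgvsTriple:
    transcript: str | None
    hgvs_g: str
    hgvs_c: str | None
    hgvs_p: str | None


@dataclass(frozen=True)
class NormalizedVariant:
    variant: GenomicVariant  # canonical anchored VCF form
    triple: HgvsTriple
    shifted: bool
    kind: str  # sub | del | ins | dup | delins


# -- parsimony --------------------------------------------------------------

def trim_parsimonious(v: GenomicVariant) -> GenomicVariant:
    """Remove shared suffix then shared prefix of ref/alt.

    At least one base is retained in each allele so indels stay anchored in
    VCF style; the position advances past trimmed prefix bases.
    """
    ref, alt, pos = v.ref, v.alt, v.pos
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == alt:
        raise HgvsError(f"{v.chrom}:{v.pos} {v.ref}>{v.alt} is not a variant")
    return GenomicVariant(v.chrom, pos, ref, alt)


def _core(v: GenomicVariant) -> tuple[int, int, str, str]:
    """Fully trimmed edit: (first changed pos, last changed pos, core ref,
    core alt).  For pure insertions core_ref is empty and the interval is
    (anchor, anchor+1), i.e. the two bases flanking the insertion point."""
    ref, alt, pos = v.ref, v.alt, v.pos
    p = 0
    while p < min(len(ref), len(alt)) and ref[p] == alt[p]:
        p += 1
    s = 0
    while (s < min(len(ref), len(alt)) - p
           and ref[len(ref) - 1 - s] == alt[len(alt) - 1 - s]):
        s += 1
    core_ref = ref[p:len(ref) - s]
    core_alt = alt[p:len(alt) - s]
    if not core_ref:  # insertion after pos + p - 1
        anchor = pos + p - 1
        return anchor, anchor + 1, core_ref, core_alt
    return pos + p, pos + p + len(core_ref) - 1, core_ref, core_alt


def _kind(core_ref: str, core_alt: str) -> str:
    if len(core_ref) == 1 and len(core_alt) == 1:
        return "sub"
    if not core_ref:
        return "ins"
    if not core_alt:
        return "del"
    return "delins"


# -- 3' shifting ------------------------------------------------------------

def shift_3prime(v: GenomicVariant, tx: TranscriptModel | None,
                 refseq: ReferenceIndex) -> GenomicVariant:
    """Shift a parsimonious variant to its most 3' equivalent position.

    3' is the transcript reading direction: genomic right for plus-strand
    transcripts (and for intergenic variants), genomic left for minus-strand
    transcripts.  Substitutions and delins events have a unique position and
    are returned unchanged.  Shifting stops at the edge of the known
    reference sequence.
    """
    v = trim_parsimonious(v)
    gs, ge, core_ref, core_alt = _core(v)
    kind = _kind(core_ref, core_alt)
    if kind in ("sub", "delins"):
        return v
    direction = -1 if tx is not None and tx.strand == "-" else 1
    chrom = v.chrom
    base = refseq.base
    if kind == "del":
        s, e = gs, ge
        if direction > 0:
            while True:
                nxt = base(chrom, e + 1)
                if nxt is None or nxt != base(chrom, s):
                    break
                s += 1
                e += 1
        else:
            while True:
                prv = base(chrom, s - 1)
                if prv is None or prv != base(chrom, e):
                    break
                s -= 1
                e -= 1
        deleted = refseq.fetch(chrom, s, e)
        anchor = base(chrom, s - 1)
        if anchor is not None:
            return GenomicVariant(chrom, s - 1, anchor + deleted, anchor)
        anchor = base(chrom, e + 1)
        if anchor is None:
            raise HgvsError(f"cannot anchor deletion at {chrom}:{s}")
        return GenomicVariant(chrom, s, deleted + anchor, anchor)
    # insertion of `ins` after position p
    p = gs
    ins = core_alt
    if direction > 0:
        while True:
            nxt = base(chrom, p + 1)
            if nxt is None or ins[0] != nxt:
                break
            ins = ins[1:] + nxt
            p += 1
    else:
        while True:
            cur = base(chrom, p)
            if cur is None or ins[-1] != cur:
                break
            ins = cur + ins[:-1]
            p -= 1
    anchor = base(chrom, p)
    if anchor is not None:
        return GenomicVariant(chrom, p, anchor, anchor + ins)
    anchor = base(chrom, p + 1)
    if anchor is None:
        raise HgvsError(f"cannot anchor insertion at {chrom}:{p}")
    return GenomicVariant(chrom, p + 1, anchor, ins + anchor)


def classify_dup(v: GenomicVariant, refseq: ReferenceIndex,
                 tx: TranscriptModel | None = None) -> str:
    """Classify a 3'-shifted insertion as ``dup`` or plain ``ins``.

    A duplication copies the reference sequence immediately 5' (in
    transcript direction) of the insertion point.
    """
    gs, _, core_ref, ins = _core(v)
    if core_ref or not ins:
        raise HgvsError("classify_dup expects a pure insertion")
    direction = -1 if tx is not None and tx.strand == "-" else 1
    if direction > 0:
        upstream = refseq.fetch(v.chrom, gs - len(ins) + 1, gs)
    else:
        upstream = refseq.fetch(v.chrom, gs + 1, gs + len(ins))
    return "dup" if upstream == ins else "ins"


# -- transcript selection ---------------------------------------------------

def select_transcript(v: GenomicVariant, txs: tuple[TranscriptModel, ...],
                      preferred: PreferredTranscriptMap) -> TranscriptModel | None:
    """Pick the reporting transcript for a variant.

    Overlapping transcripts named in the preferred map win; among several
    candidates the one whose nearest exon is closest to the variant is
    chosen (0 for exonic), remaining ties broken by accession.  Returns
    None for intergenic variants.
    """
    gs, ge, _, _ = _core(trim_parsimonious(v))
    overlapping = [t for t in txs if t.overlaps(v.chrom, gs, ge)]
    if not overlapping:
        return None
    pref_accs = preferred.accessions()
    pool = [t for t in overlapping if t.accession in pref_accs] or overlapping
    return min(pool, key=lambda t: (t.exon_distance(gs), t.accession))


# -- rendering --------------------------------------------------------------

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Ter",
}

_RC = str.maketrans("ACGT", "TGCA")


def _rc(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _c_label(tx: TranscriptModel, gpos: int) -> str:
    n, off = tx.genomic_to_tx(gpos)
    if n < tx.cds_start_c:
        label = str(n - tx.cds_start_c)  # negative, 5' UTR
    elif n > tx.cds_end_c:
        label = f"*{n - tx.cds_end_c}"
    else:
        label = str(n - tx.cds_start_c + 1)
    if off > 0:
        label += f"+{off}"
    elif off < 0:
        label += str(off)
    return label


def _c_is_coding(tx: TranscriptModel, gpos: int) -> int | None:
    """CDS position (1-based) of an exonic coding base, else None."""
    n, off = tx.genomic_to_tx(gpos)
    if off != 0 or not tx.cds_start_c <= n <= tx.cds_end_c:
        return None
    return n - tx.cds_start_c + 1


def _g_string(chrom: str, gs: int, ge: int, core_ref: str, core_alt: str,
              kind: str, dup_span: tuple[int, int] | None) -> str:
    if kind == "sub":
        return f"{chrom}:g.{gs}{core_ref}>{core_alt}"
    if kind == "del":
        loc = f"{gs}" if gs == ge else f"{gs}_{ge}"
        return f"{chrom}:g.{loc}del"
    if kind == "dup":
        s, e = dup_span
        loc = f"{s}" if s == e else f"{s}_{e}"
        return f"{chrom}:g.{loc}dup"
    if kind == "ins":
        return f"{chrom}:g.{gs}_{ge}ins{core_alt}"
    loc = f"{gs}" if gs == ge else f"{gs}_{ge}"
    return f"{chrom}:g.{loc}delins{core_alt}"


def to_hgvs(v: GenomicVariant, tx: TranscriptModel,
            refseq: ReferenceIndex, three_letter: bool = False,
            flank: int = 10000) -> HgvsTriple:
    """Render a canonical (trimmed, transcript-direction shifted,
    dup-classified) variant as an (accession, g., c., p.) triple."""
    gs, ge, core_ref, core_alt = _core(v)
    if not tx.overlaps(v.chrom, gs, ge, flank=flank):
        raise HgvsError(
            f"variant {v.chrom}:{v.pos} outside transcript {tx.accession}")
    kind = _kind(core_ref, core_alt)
    minus = tx.strand == "-"
    dup_span = None
    if kind == "ins" and classify_dup(v, refseq, tx) == "dup":
        kind = "dup"
        n = len(core_alt)
        dup_span = (gs - n + 1, gs) if not minus else (gs + 1, gs + n)

    hgvs_g = _g_string(v.chrom, gs, ge, core_ref, core_alt, kind, dup_span)

    # transcript-ordered genomic endpoints of the event
    if kind == "dup":
        span = dup_span
    elif kind == "ins":
        span = (gs, ge)  # the two bases flanking the insertion point
    else:
        span = (gs, ge)
    ga, gb = span if not minus else (span[1], span[0])
    ca, cb = _c_label(tx, ga), _c_label(tx, gb)
    t_ref = core_ref if not minus else _rc(core_ref)
    t_alt = core_alt if not minus else _rc(core_alt)
    acc = tx.accession
    if kind == "sub":
        hgvs_c = f"{acc}:c.{ca}{t_ref}>{t_alt}"
    elif kind == "del":
        loc = ca if ga == gb else f"{ca}_{cb}"
        hgvs_c = f"{acc}:c.{loc}del"
    elif kind == "dup":
        loc = ca if ga == gb else f"{ca}_{cb}"
        hgvs_c = f"{acc}:c.{loc}dup"
    elif kind == "ins":
        hgvs_c = f"{acc}:c.{ca}_{cb}ins{t_alt}"
    else:
        loc = ca if ga == gb else f"{ca}_{cb}"
        hgvs_c = f"{acc}:c.{loc}delins{t_alt}"

    hgvs_p = predict_protein(hgvs_c.split(":", 1)[1], tx, three_letter)
    return HgvsTriple(acc, hgvs_g, hgvs_c, hgvs_p)


# -- protein consequence ----------------------------------------------------

_C_SUB = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")
_C_DELINS = re.compile(r"^c\.(\d+)(?:_(\d+))?delins([ACGT]+)$")
_C_DEL = re.compile(r"^c\.(\d+)(?:_(\d+))?del$")
_C_INS = re.compile(r"^c\.(\d+)_(\d+)ins([ACGT]+)$")
_C_DUP = re.compile(r"^c\.(\d+)(?:_(\d+))?dup$")


def _translate(seq: str) -> str:
    prot = str(Seq(seq[:len(seq) // 3 * 3]).translate())
    stop = prot.find("*")
    return prot if stop < 0 else prot[:stop + 1]


def _aa(aa: str, three_letter: bool) -> str:
    return _AA3[aa] if three_letter else aa


def predict_protein(c_variant: str, tx: TranscriptModel,
                    three_letter: bool = False) -> str | None:
    """Protein consequence of a coding c. variant (our own emitted forms).

    Returns None for intronic/UTR variants.  In-frame changes are named by
    diffing the reference and mutated protein sequences; frameshifts count
    codons to the first downstream stop; a disrupted initiator codon is
    rendered ``p.?``.
    """
    cds = tx.cds_seq
    clen = len(cds)

    def _check(a: int, b: int) -> bool:
        return 1 <= a <= b <= clen

    m = _C_SUB.match(c_variant)
    if m:
        p, ref, alt = int(m.group(1)), m.group(2), m.group(3)
        if not _check(p, p):
            return None
        if cds[p - 1] != ref:
            raise HgvsError(f"{c_variant}: reference base mismatch")
        mut = cds[:p - 1] + alt + cds[p:]
    elif (m := _C_DELINS.match(c_variant)):
        a = int(m.group(1))
        b = int(m.group(2)) if m.group(2) else a
        if not _check(a, b):
            return None
        mut = cds[:a - 1] + m.group(3) + cds[b:]
    elif (m := _C_DEL.match(c_variant)):
        a = int(m.group(1))
        b = int(m.group(2)) if m.group(2) else a
        if not _check(a, b):
            return None
        mut = cds[:a - 1] + cds[b:]
    elif (m := _C_INS.match(c_variant)):
        a = int(m.group(1))
        if not _check(a, a):
            return None
        mut = cds[:a] + m.group(3) + cds[a:]
    elif (m := _C_DUP.match(c_variant)):
        a = int(m.group(1))
        b = int(m.group(2)) if m.group(2) else a
        if not _check(a, b):
            return None
        mut = cds[:b] + cds[a - 1:b] + cds[b:]
    else:
        return None  # intronic / UTR / unsupported form

    ref_p = _translate(cds)
    alt_p = _translate(mut)
    if (len(mut) - clen) % 3 != 0:
        # frameshift: first differing residue, count to new stop
        i = 0
        while i < min(len(ref_p), len(alt_p)) and ref_p[i] == alt_p[i]:
            i += 1
        if i == 0:
            return "p.?"  # initiator disrupted
        r = _aa(ref_p[i], three_letter) if i < len(ref_p) else "Ter" if three_letter else "*"
        if i >= len(alt_p):
            return f"p.{r}{i + 1}fs*?"
        a = alt_p[i]
        if a == "*":
            return f"p.{r}{i + 1}{_aa('*', three_letter)}"
        stop = alt_p.find("*", i)
        ext = f"*{stop - i + 1}" if stop >= 0 else "*?"
        return f"p.{r}{i + 1}{_aa(a, three_letter)}fs{ext}"

    if ref_p == alt_p:
        return "p.(=)"
    np_ = 0
    while np_ < min(len(ref_p), len(alt_p)) and ref_p[np_] == alt_p[np_]:
        np_ += 1
    ns = 0
    while (ns < min(len(ref_p), len(alt_p)) - np_
           and ref_p[len(ref_p) - 1 - ns] == alt_p[len(alt_p) - 1 - ns]):
        ns += 1
    ref_core = ref_p[np_:len(ref_p) - ns]
    alt_core = alt_p[np_:len(alt_p) - ns]
    i = np_  # 0-based index of first changed residue
    if i == 0 and ref_p[0] == "M" and ref_core:
        return "p.?"
    if len(ref_core) == 1 and len(alt_core) == 1:
        return f"p.{_aa(ref_core[0], three_letter)}{i + 1}{_aa(alt_core[0], three_letter)}"
    if not alt_core:
        a_lab = f"{_aa(ref_core[0], three_letter)}{i + 1}"
        if len(ref_core) == 1:
            return f"p.{a_lab}del"
        b_lab = f"{_aa(ref_core[-1], three_letter)}{i + len(ref_core)}"
        return f"p.{a_lab}_{b_lab}del"
    if not ref_core:
        left = f"{_aa(ref_p[i - 1], three_letter)}{i}"
        right = f"{_aa(ref_p[i], three_letter)}{i + 1}"
        ins = "".join(_aa(x, three_letter) for x in alt_core)
        return f"p.{left}_{right}ins{ins}"
    ins = "".join(_aa(x, three_letter) for x in alt_core)
    a_lab = f"{_aa(ref_core[0], three_letter)}{i + 1}"
    if len(ref_core) == 1:
        return f"p.{a_lab}delins{ins}"
    b_lab = f"{_aa(ref_core[-1], three_letter)}{i + len(ref_core)}"
    return f"p.{a_lab}_{b_lab}delins{ins}"


# -- top level --------------------------------------------------------------

def normalize(v: GenomicVariant, txs: tuple[TranscriptModel, ...],
              preferred: PreferredTranscriptMap, refseq: ReferenceIndex,
              three_letter: bool = False) -> NormalizedVariant:
    """Trim, select transcript, 3' shift, dup-classify and render.

    Idempotent: normalizing the canonical variant returns it unchanged.
    """
    trimmed = trim_parsimonious(v)
    tx = select_transcript(trimmed, txs, preferred)
    shifted_v = shift_3prime(trimmed, tx, refseq)
    _, _, core_ref, core_alt = _core(shifted_v)
    kind = _kind(core_ref, core_alt)
    if kind == "ins":
        kind = classify_dup(shifted_v, refseq, tx)
    if tx is not None:
        triple = to_hgvs(shifted_v, tx, refseq, three_letter)
    else:
        gs, ge, cr, ca = _core(shifted_v)
        dup_span = None
        if kind == "dup":
            dup_span = (gs - len(ca) + 1, gs)
        triple = HgvsTriple(None,
                            _g_string(shifted_v.chrom, gs, ge, cr, ca, kind,
                                      dup_span),
                            None, None)
    return NormalizedVariant(shifted_v, triple,
                             shifted=shifted_v != trimmed, kind=kind)
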