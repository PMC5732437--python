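"""Normalization engine: parsimony, 3' shifting, dup classification,
transcript selection, HGVS rendering and protein consequences.

The uniqueness tests rely on an enumeration oracle that, given a reference
window and its mutated counterpart, exhaustively lists every VCF-style
(pos, ref, alt) encoding that reproduces the mutation; all of them must
normalize to one identical canonical variant and HGVS triple.
"""

import numpy as np
import pytest

from amplicall.hgvs import (GenomicVariant, HgvsError, classify_dup,
                            normalize, predict_protein, select_transcript,
                            shift_3prime, to_hgvs, trim_parsimonious)
from amplicall.merge import revcomp
from amplicall.panel import (AmpliconDef, Panel, PreferredTranscriptMap,
                             TranscriptModel)
from amplicall.simulate import make_toy_coding_panel

FWD = "ACGTTGCAAC"
REV = "TGGATCCAGT"


def ref_panel(insert, chrom="chrX", start=501):
    """One-amplicon panel whose insert is the given sequence."""
    ref = FWD + insert + revcomp(REV)
    amp = AmpliconDef("T1", chrom, start, start + len(ref) - 1, FWD, REV, ref)
    return Panel((amp,))


def apply_edit(ref_win, g0, v: GenomicVariant):
    """Apply a VCF-style edit to a reference window starting at g0."""
    off = v.pos - g0
    assert ref_win[off:off + len(v.ref)] == v.ref
    return ref_win[:off] + v.alt + ref_win[off + len(v.ref):]


def enumerate_encodings(ref_win, mut_win, g0, max_ref_len=8):
    """Every (pos, ref, alt) with non-empty alleles reproducing mut_win."""
    out = []
    delta = len(mut_win) - len(ref_win)
    for i in range(len(ref_win)):
        if mut_win[:i] != ref_win[:i]:
            break
        for rl in range(0, max_ref_len + 1):
            if i + rl > len(ref_win):
                break
            al = rl + delta
            if al < 0:
                continue
            if mut_win[i + al:] != ref_win[i + rl:]:
                continue
            ref, alt = ref_win[i:i + rl], mut_win[i:i + al]
            if ref and alt and ref != alt:
                out.append(GenomicVariant("chrX", g0 + i, ref, alt))
    return out


# -- parsimony --------------------------------------------------------------

@pytest.mark.parametrize("v,expected", [
    (GenomicVariant("c", 100, "CTT", "CT"), GenomicVariant("c", 100, "CT", "C")),
    (GenomicVariant("c", 100, "G", "A"), GenomicVariant("c", 100, "G", "A")),
    (GenomicVariant("c", 50, "ACAC", "AC"), GenomicVariant("c", 50, "ACA", "A")),
    (GenomicVariant("c", 10, "TGGT", "TGAT"), GenomicVariant("c", 12, "G", "A")),
])
def test_trim_parsimonious(v, expected):
    assert trim_parsimonious(v) == expected


def test_trim_rejects_non_variant():
    with pytest.raises(HgvsError):
        trim_parsimonious(GenomicVariant("c", 5, "ACG", "ACG"))


def test_trim_agrees_with_enumeration_oracle():
    """All paddings of one deletion trim to edits with identical effect."""
    ref_win = "GGACTTTCAG"
    mut_win = "GGACTTCAG"  # delete one T
    encs = enumerate_encodings(ref_win, mut_win, 100)
    assert len(encs) > 3
    for enc in encs:
        t = trim_parsimonious(enc)
        assert apply_edit(ref_win, 100, t) == mut_win


# -- 3' shifting ------------------------------------------------------------

def test_homopolymer_deletion_shifts_right_without_transcript():
    insert = "GGC" + "AAAAAA" + "TCG" + "C" * 20
    panel = ref_panel(insert)
    refidx = panel.reference()
    hp_start = 501 + len(FWD) + 3  # genomic pos of first A
    # deletion of the first A, anchored at the base before
    v = GenomicVariant("chrX", hp_start - 1, "CA", "C")
    shifted = shift_3prime(v, None, refidx)
    assert shifted.pos == hp_start + 4  # anchored at the 5th A, deleting the 6th
    assert (shifted.ref, shifted.alt) == ("AA", "A")


def test_homopolymer_deletion_shifts_left_for_minus_strand():
    insert = "GGC" + "AAAAAA" + "TCG" + "C" * 20
    panel = ref_panel(insert)
    refidx = panel.reference()
    hp_start = 501 + len(FWD) + 3
    minus_tx = TranscriptModel(
        "NM_m.1", "GM", "chrX", "-",
        ((hp_start - 10, hp_start + 19),), 4, 27, "A" * 30)
    v = GenomicVariant("chrX", hp_start + 4, "AA", "A")  # rightmost encoding
    shifted = shift_3prime(v, minus_tx, refidx)
    assert shifted.pos == hp_start - 1
    assert (shifted.ref, shifted.alt) == ("CA", "C")


def test_snv_not_shifted():
    panel = ref_panel("GGCATTTCAG" + "C" * 20)
    v = GenomicVariant("chrX", 520, panel.amplicons[0].ref_seq[19], "A")
    if v.ref == "A":
        v = GenomicVariant("chrX", 520, v.ref, "G")
    assert shift_3prime(v, None, panel.reference()) == trim_parsimonious(v)


def test_shift_enumeration_oracle_plus_and_minus():
    """Every equivalent encoding of one homopolymer deletion shifts to the
    same canonical position: rightmost for plus strand, leftmost (minimal
    genomic coordinate) for minus strand."""
    insert = "GGC" + "AAAAA" + "TCGTA" + "C" * 15
    panel = ref_panel(insert)
    refidx = panel.reference()
    g0 = 501
    ref_win = panel.amplicons[0].ref_seq
    hp = g0 + len(FWD) + 3
    mut_win = apply_edit(ref_win, g0, GenomicVariant("chrX", hp - 1, "CA", "C"))
    encs = enumerate_encodings(ref_win, mut_win, g0)
    minus_tx = TranscriptModel("NM_m.1", "GM", "chrX", "-",
                               ((hp - 5, hp + 24),), 4, 27, "A" * 30)
    plus = {shift_3prime(trim_parsimonious(e), None, refidx) for e in encs}
    minus = {shift_3prime(trim_parsimonious(e), minus_tx, refidx)
             for e in encs}
    assert len(plus) == 1 and len(minus) == 1
    (p,), (m,) = plus, minus
    assert p.pos > m.pos  # plus shifts right, minus shifts left


# -- dup classification -----------------------------------------------------

def test_insertion_duplicating_upstream_is_dup():
    insert = "GGCATGTCAG" + "C" * 20
    panel = ref_panel(insert)
    refidx = panel.reference()
    g_tg_end = 501 + len(FWD) + 5  # position of the G in ...TG
    anchor = refidx.base("chrX", g_tg_end)
    v = GenomicVariant("chrX", g_tg_end, anchor, anchor + "TG")
    assert classify_dup(v, refidx) == "dup"


def test_insertion_not_matching_upstream_is_ins():
    insert = "GGCACATCAG" + "C" * 20
    panel = ref_panel(insert)
    refidx = panel.reference()
    pos = 501 + len(FWD) + 5
    anchor = refidx.base("chrX", pos)
    v = GenomicVariant("chrX", pos, anchor, anchor + "TG")
    assert classify_dup(v, refidx) == "ins"


def test_single_base_self_duplication():
    insert = "GGCATTCAGA" + "C" * 20
    panel = ref_panel(insert)
    refidx = panel.reference()
    pos = 501 + len(FWD) + 4  # a T
    assert refidx.base("chrX", pos) == "T"
    v = GenomicVariant("chrX", pos, "T", "TT")
    assert classify_dup(v, refidx) == "dup"


# -- transcript selection ---------------------------------------------------

def _tx(acc, gene, exons, chrom="chrX"):
    total = sum(e - s + 1 for s, e in exons)
    return TranscriptModel(acc, gene, chrom, "+", tuple(exons),
                           4, 4 + ((total - 6) // 3) * 3 - 1, "A" * total)


def test_single_overlapping_transcript_selected():
    tx = _tx("NM_1.1", "G1", [(100, 199)])
    v = GenomicVariant("chrX", 150, "A", "T")
    assert select_transcript(v, (tx,), PreferredTranscriptMap()) is tx


def test_preferred_transcript_wins():
    tx_a = _tx("NM_1.1", "G1", [(100, 199)])
    tx_b = _tx("NM_2.1", "G1", [(100, 199)])
    pref = PreferredTranscriptMap({"G1": "NM_2.1"})
    v = GenomicVariant("chrX", 150, "A", "T")
    assert select_transcript(v, (tx_a, tx_b), pref).accession == "NM_2.1"


def test_exon_distance_breaks_preferred_ties():
    # variant at 250: 10 bp past txA's exon end (240), 50 bp before txB's
    tx_a = _tx("NM_1.1", "G1", [(141, 240), (401, 460)])
    tx_b = _tx("NM_2.1", "G2", [(1, 100), (300, 359)])
    pref = PreferredTranscriptMap({"G1": "NM_1.1", "G2": "NM_2.1"})
    v = GenomicVariant("chrX", 250, "A", "T")
    assert select_transcript(v, (tx_a, tx_b), pref).accession == "NM_1.1"


def test_intergenic_variant_selects_none():
    tx = _tx("NM_1.1", "G1", [(100, 199)])
    v = GenomicVariant("chrX", 5000, "A", "T")
    assert select_transcript(v, (tx,), PreferredTranscriptMap()) is None


# -- rendering --------------------------------------------------------------

def test_intronic_snv_offset_notation(braf_panel):
    panel, info = braf_panel
    tx = panel.transcripts[0]
    refidx = panel.reference()
    # 3 bases past the end of exon 1 (genomic 2800 = c.1700)
    v = GenomicVariant("chrB", 2803, "A", "G")
    triple = to_hgvs(v, tx, refidx)
    assert triple.hgvs_c == "NM_900001.1:c.1700+3A>G"
    assert triple.hgvs_p is None
    # 1 base before the start of exon 2 (genomic 5041 = c.1701)
    v2 = GenomicVariant("chrB", 5040, panel.reference().base("chrB", 5040),
                        "T")
    if v2.ref == "T":
        v2 = GenomicVariant("chrB", 5040, v2.ref, "C")
    triple2 = to_hgvs(v2, tx, refidx)
    assert ":c.1701-1" in triple2.hgvs_c


def test_duplication_renders_c21_22dup():
    """An insertion copying c.21_22 normalizes to the c.21_22dup name."""
    cds = "ATG" + "GAACTTCATCACGGA" + "ATT" + "GCA" + "CTTCCT" + "TAA"
    panel, info = make_toy_coding_panel(seed=5, strand="+", cds_seq=cds,
                                        utr5=12, utr3=12)
    tx = panel.transcripts[0]
    refidx = panel.reference()
    exon_start = info["exon_g"][0]
    # c.21 and c.22 are 'T','G'; insert "TG" after c.20 (an equivalent,
    # un-shifted encoding of the duplication)
    g_c20 = exon_start + 12 + 20 - 1
    anchor = refidx.base(tx.chrom, g_c20)
    v = GenomicVariant(tx.chrom, g_c20, anchor, anchor + "TG")
    norm = normalize(v, panel.transcripts, panel.preferred, refidx)
    assert norm.kind == "dup"
    assert norm.triple.hgvs_c.endswith(":c.21_22dup")


def test_minus_strand_coding_substitution(toy_minus_panel):
    panel, info = toy_minus_panel
    tx = panel.transcripts[0]
    refidx = panel.reference()
    # c.10 on a minus-strand transcript: genomic base is the complement
    n = tx.cds_start_c + 9  # spliced position of c.10
    g = info["exon_g"][1] - (n - 1)  # minus strand: tx runs right to left
    t_base = tx.spliced_seq[n - 1]
    g_base = revcomp(t_base)
    assert refidx.base(tx.chrom, g) == g_base
    new_t = {"A": "G", "C": "T", "G": "A", "T": "C"}[t_base]
    v = GenomicVariant(tx.chrom, g, g_base, revcomp(new_t))
    triple = to_hgvs(v, tx, refidx)
    assert triple.hgvs_c == f"{tx.accession}:c.10{t_base}>{new_t}"


# -- protein consequences ---------------------------------------------------

def test_braf_codon600_consequences(braf_panel):
    panel, _ = braf_panel
    tx = panel.transcripts[0]
    assert predict_protein("c.1798G>A", tx) == "p.V600M"
    assert predict_protein("c.1799T>G", tx) == "p.V600G"
    assert predict_protein("c.1798_1799delinsAG", tx) == "p.V600R"


def test_synonymous_substitution(braf_panel):
    panel, _ = braf_panel
    tx = panel.transcripts[0]
    # GTG -> GTA still encodes valine
    assert predict_protein("c.1800G>A", tx) == "p.(=)"


def test_frameshift_counts_to_stop(braf_panel):
    panel, _ = braf_panel
    tx = panel.transcripts[0]
    p = predict_protein("c.1798del", tx)
    assert p is not None and "fs" in p and p.startswith("p.V600")


def test_inframe_deletion(braf_panel):
    panel, _ = braf_panel
    tx = panel.transcripts[0]
    p = predict_protein("c.1798_1800del", tx)
    assert p is not None and p.endswith("del")


def test_three_letter_rendering(braf_panel):
    panel, _ = braf_panel
    tx = panel.transcripts[0]
    assert predict_protein("c.1798G>A", tx, three_letter=True) == "p.Val600Met"


def test_intronic_c_variant_has_no_protein(braf_panel):
    panel, _ = braf_panel
    tx = panel.transcripts[0]
    assert predict_protein("c.1700+3A>G", tx) is None


# -- full normalization -----------------------------------------------------

def test_normalize_idempotent(braf_panel):
    panel, info = braf_panel
    refidx = panel.reference()
    g = info["c1798_g"]
    for v in (GenomicVariant("chrB", g, "G", "A"),
              GenomicVariant("chrB", g, "GT", "AG"),
              GenomicVariant("chrB", g - 1, "AG", "A")):
        n1 = normalize(v, panel.transcripts, panel.preferred, refidx)
        n2 = normalize(n1.variant, panel.transcripts, panel.preferred, refidx)
        assert (n1.variant, n1.triple, n1.kind) == (n2.variant, n2.triple,
                                                    n2.kind)


def test_normalization_uniqueness_over_random_indels():
    """Random small indels: every enumerated VCF encoding normalizes to one
    identical canonical variant and triple, and the canonical edit
    reproduces the mutated sequence (round trip)."""
    rng = np.random.default_rng(12345)
    bases = "ACGT"
    n_cases = 0
    for trial in range(60):
        insert = "".join(bases[i] for i in rng.integers(0, 4, size=60))
        panel = ref_panel(insert)
        refidx = panel.reference()
        amp = panel.amplicons[0]
        g0 = amp.start
        ref_win = amp.ref_seq
        off = int(rng.integers(20, 45))
        if rng.random() < 0.5:
            dlen = int(rng.integers(1, 5))
            edit = GenomicVariant("chrX", g0 + off - 1,
                                  ref_win[off - 1:off + dlen],
                                  ref_win[off - 1])
        else:
            ins = "".join(bases[i] for i in rng.integers(0, 4, size=int(
                rng.integers(1, 5))))
            edit = GenomicVariant("chrX", g0 + off - 1, ref_win[off - 1],
                                  ref_win[off - 1] + ins)
        mut_win = apply_edit(ref_win, g0, edit)
        encs = enumerate_encodings(ref_win, mut_win, g0)
        norms = {
            (n.variant, n.triple.hgvs_g, n.kind)
            for n in (normalize(e, (), PreferredTranscriptMap(), refidx)
                      for e in encs)}
        assert len(norms) == 1, f"trial {trial}: {norms}"
        canonical = next(iter(norms))[0]
        assert apply_edit(ref_win, g0, canonical) == mut_win
        n_cases += len(encs)
    assert n_cases >= 300
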