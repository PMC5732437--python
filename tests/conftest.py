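import pytest

from amplicall.calling import RawVariant
from amplicall.merge import ReadPair, revcomp
from amplicall.simulate import (make_braf_like_panel, make_panel,
                                make_toy_coding_panel, quality_profile)


@pytest.fixture(scope="session")
def small_panel():
    """Two-amplicon random panel (200 bp inserts, 20 bp primers)."""
    return make_panel(n_amplicons=2, insert_len=200, primer_len=20, seed=11)


@pytest.fixture(scope="session")
def braf_panel():
    """Single-amplicon panel with the synthetic BRAF-like transcript."""
    return make_braf_like_panel(seed=7)


@pytest.fixture(scope="session")
def toy_minus_panel():
    """Single-exon minus-strand toy transcript inside one amplicon."""
    return make_toy_coding_panel(seed=3, strand="-", gene="TOYM",
                                 accession="NM_910002.1", chrom="chrM1")


def perfect_pair(amplicon, fragment=None, read_len=150, pair_id="p"):
    """Error-free read pair from a fragment (default: the amplicon ref)."""
    frag = fragment if fragment is not None else amplicon.ref_seq
    rl = min(read_len, len(frag))
    return ReadPair(pair_id,
                    frag[:rl], quality_profile(rl, 1),
                    revcomp(frag)[:rl], quality_profile(rl, 2))


def mutate(amplicon, pos, alt):
    """Fragment equal to the amplicon reference with a substitution at the
    1-based genomic position ``pos``."""
    off = pos - amplicon.start
    seq = amplicon.ref_seq
    assert seq[off] != alt
    return seq[:off] + alt + seq[off + 1:]


def other_base(base):
    return {"A": "C", "C": "G", "G": "T", "T": "A"}[base]


def planted_snv(amplicon, offset_in_insert=50):
    """A substitution RawVariant inside the amplicon insert."""
    pos = amplicon.insert_start + offset_in_insert
    ref = amplicon.ref_seq[pos - amplicon.start]
    return RawVariant(amplicon.chrom, pos, ref, other_base(ref),
                      amplicon.name)
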