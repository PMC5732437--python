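# Methods

## Model and assumptions

`amplicall` targets amplicon assays in which each sequenced fragment is a
PCR product delimited by a known forward/reverse primer pair, and the
primers are separated by slightly more than one read length so the two
mates of a pair overlap.  Three assumptions follow and are relied on
throughout:

- both mates of a pair derive from one DNA molecule, so variants observed
  on one merged read are in phase by construction;
- the first bases of read 1 and read 2 are the forward and reverse primer
  sequences (as sequenced), so amplicon identity can be decided by
  Hamming comparison of read prefixes without genome-wide alignment;
- primer bases are synthetic (they come from the oligo, not the
  template), so apparent variants inside primer-binding regions are
  artefacts and are dropped.

Pairs that fail to merge or to match a primer pair are counted in the run
statistics and excluded from calling; depth is therefore a count of
merged, assigned pairs whose alignment covers the locus, and the allele
frequency of a call is `supporting pairs / covering pairs`.  When a locus
is tiled by several amplicons, support and coverage are summed per locus
across amplicons.  Calls whose different raw VCF encodings normalize to
the same canonical edit are merged before reporting: supporting counts
add, and the depth is the widest per-encoding estimate (the encodings
come from the same covering reads, so summing depths would double-count).

## Alignment

Both merging and calling use one affine-gap Smith–Waterman implementation
(numba kernel; full DP matrices, fine for read-scale sequences).  A gap of
length L costs `gap_open + (L-1)*gap_extend`.  Defaults: match +2,
mismatch −2, gap open −3, gap extend −1 — conventional striped-SW library
defaults; all configurable.  Determinism is guaranteed by explicit
tie-breaks: among equal-scoring alignments the one ending earliest in the
first sequence wins, then earliest in the second; the traceback prefers
diagonal moves and closes gaps as early as possible, which also minimizes
gap openings along the chosen path.  The test suite checks score
equality against an independent pure-Python Gotoh oracle and against
Biopython's local aligner.

Merging aligns read 1 against the reverse complement of read 2 and
accepts the overlap when it spans ≥ `min_overlap` (15) bases at
≥ `min_overlap_identity` (0.90) identity; both guards reject spurious
overlaps between unrelated reads at typical amplicon read lengths.
Consensus arithmetic — agreeing bases sum qualities capped at Q60,
disagreeing bases keep the higher-quality base at quality |q₁−q₂|, exact
ties keep the read-1 base at Q2 — is a package definition chosen so that
consensus quality reflects corroboration while never overstating a
disagreement.

Per-read calling walks the edit operations of the read-versus-amplicon
alignment.  Each mismatched base becomes its own substitution record and
each gap run one anchored indel; emitting substitutions per base (rather
than as multi-base runs) is what lets the phasing step both build the
compound delins and report each constituent individually.  Reads whose
best alignment covers less than half their length are counted as
unalignable and discarded.

## Phasing

Variants from one merged read are sorted and grouped transitively
wherever the gap between one variant's reference end and the next
variant's start is ≤ `phase_window` (default 15 bases; the window is
measured between reference spans, an explicit choice since "within N
bases" leaves the endpoints open).  Groups of two or more produce a
parent delins spanning the first to last changed reference base, with the
alternate built by applying the constituent edits to the reference span.
Parent and constituents are all reported, sharing an `MNP_LINK`; each
record counts exactly the reads exhibiting it, so a read carrying only
one constituent contributes to that constituent alone.

## Read-pair cache

Results are cached keyed by the raw `(seq1, seq2)` pair — qualities are
deliberately excluded, so the first-seen pair's quality-resolved
consensus is reused for sequence-identical repeats.  The consequence is
documented and bounded: quality differences can only matter at
disagreeing overlap bases, and the simulator emits identical sequence
pairs with identical (cycle-determined) qualities, under which cached and
uncached runs are byte-identical (tested).

## Normalization and HGVS

A VCF tuple is reduced to a unique canonical form in four steps: trim
shared suffix then prefix (keeping one anchor base per allele for
indels); select the reporting transcript — overlapping transcripts named
in the preferred-transcript map win, ties go to the transcript whose
nearest exon is closest to the variant (genomic distance, 0 if exonic),
then to the lexicographically smallest accession; shift pure indels as
far 3′ as possible in the transcript reading direction (genomic right for
plus-strand and intergenic variants, genomic left for minus-strand
transcripts), bounded by the known reference sequence; and re-classify an
insertion as a duplication when it copies the reference immediately 5′
(transcript direction) of the insertion point.

The genomic (g.) name deliberately mirrors the transcript-shifted
position even on minus-strand transcripts, so genomic and cDNA positions
always agree; intergenic variants are right-shifted on the plus strand
and reported with HGVSg only.  c. positions map through exon geometry
with intronic offsets (`c.N+k` / `c.N−k`, anchored to the nearer exon
boundary) and UTR notation (`c.−k`, `c.*k`).  Protein consequences are
computed by applying the coding edit to the CDS and diffing the
translated proteins: substitutions, in-frame del/ins/delins, synonymous
(`p.(=)`), frameshifts with distance to the first new stop
(`p.X123Yfs*N`), and `p.?` for a disrupted initiator codon.  One-letter
amino acids are the default (`p.V600R`); a flag switches to three-letter.
The engine is local and offline; any component with the same operation
signatures (for instance a client for a remote normalization service)
can be substituted.

Normalization is idempotent, and an enumeration oracle in the tests
verifies uniqueness: every VCF encoding of a random small indel —
generated exhaustively by re-deriving all (pos, ref, alt) triples that
reproduce the mutated sequence — maps to one identical canonical variant
and HGVS name, and applying the canonical edit reproduces the mutation.

## Annotation

Annotation fields use hierarchical dotted names and are fetched per
HGVSg id through a backend contract: an offline fixture backend (local
JSON keyed by HGVSg) used by all tests, and a batch HTTP client (100 ids
per request, one retry) that is never exercised in the suite.  If the
service is unreachable the run completes with an unannotated VCF, a
warning, and a distinct exit status (4).  INFO keys keep their dots;
characters outside `[A-Za-z0-9_.]` become underscores and values are
percent-encoded for VCF-reserved characters, so every written VCF
re-parses strictly (validated with pysam in the tests).

## Synthetic data

The generator emulates the assay's geometry, not its chemistry.  Panels
are random sequences with primers kept ≥7 mismatches apart pairwise
(twice the default primer-mismatch tolerance, so assignment is
unambiguous); default dimensions are 200 bp inserts with 20 bp primers
and 150 bp reads, giving a 60 bp overlap.  Base qualities follow a
deterministic declining profile (read 1: 38→28, read 2: 36→26),
emulating quality decay across cycles and the poorer second read.
Sequencing errors are uniform random substitutions at a configurable
per-base rate, never injected into primer cycles.  Planted variants are
assigned to pairs either binomially (realistic default) or exactly
(`round(fraction × depth)` pairs, used where a deterministic count is
wanted); simulated depth defaults to 2000 pairs per amplicon, typical of
deep amplicon panels.  A BRAF-like two-exon transcript fixture (synthetic
accession NM_900001.1, plus strand) places a GTG valine codon at
c.1798-1800; the real gene is minus-strand, but the worked example lives
entirely in c./p. space, and minus-strand mapping and shifting are
exercised by separate toy transcripts.

Not modelled, and therefore not demonstrated by passing tests: PCR
chimeras and polymerase stutter, strand- or context-specific error
profiles, primer-site mutations in the template, copy-number effects and
replicate-pair artefacts.  Real data will show recurrent primer-adjacent
false positives that the simulator cannot produce.

## Numerical and degenerate-input choices

Threshold comparisons are inclusive (`vaf ≥ min_vaf`,
`alt_pairs ≥ min_reads`) to avoid floating-point edge surprises; AF is
serialized with `%.6g`.  Zero-coverage loci report VAF 0.  Insertions or
deletions at the very first reference base are re-anchored on the right;
indels whose shift reaches the edge of the known reference stop there.
Empty FASTQ inputs produce an empty call set with valid statistics;
mate-count mismatches are fatal.  Default problem sizes in the tests and
the acceptance script (single amplicons, 2000 pairs, 30-gap scans) were
chosen as the smallest sizes at which every quantity of interest is
exact or statistically stable.

## Known limitations

Single-threaded; one sample per run; no gVCF, no liftover, no RNA-level
notation, no adapter/quality trimming (inputs are assumed
quality-controlled upstream); unmergeable pairs are discarded rather than
rescued as single-end reads, consistent with an assay design that
guarantees overlap; the HGVS parser accepts only the forms this package
emits.
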