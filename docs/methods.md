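# Methods

This note documents the models and procedures implemented in rtdforge, the
parameters that matter, the design choices made where the design was
genuinely open, and what the simulation-based tests do and do not show.

## Coordinates and containers

All coordinates are 0-based half-open; converters to and from 1-based
closed formats (GTF, STAR `SJ.out.tab`) live only in `io_formats`. Exon
blocks are stored in genomic (leftmost-first) order on both strands; 5'
and 3' ends are derived strand-aware, and the "position" of an end is the
half-open boundary of the outermost block on that side. Substitution
positions are recovered from the MD tag when present, otherwise by base
comparison against the genome; insertions and deletions are consumed
during the walk but never counted as mismatches, since only substitutions
near junction boundaries are used as evidence of mis-mapping.

## High-confidence splice junctions

A long-read junction is high-confidence when all three hold:

1. canonical sense-strand dinucleotides — (GT,AG), (GC,AG) or (AT,AC);
   the set is configurable but defaults to the standard spliceosomal
   triple; any N fails;
2. at least one supporting read with **zero substitutions within 10 nt of
   both intron boundaries, on the exonic side**. The window spans only
   exonic flanks because junction mis-mapping caused by local errors
   manifests as exon-edge mismatches. A read must be clean at both
   boundaries simultaneously (the conservative reading of "upstream and
   downstream");
3. no template-switch signature: Hamming distance > 1 both between the
   last 8 sense bases of the upstream exon and the last 8 bases of the
   intron, and between the first 8 bases of the intron and the first 8
   bases of the downstream exon. Contexts shorter than 8 nt at contig
   edges are padded with side-specific sentinels that can never match, so
   truncated contexts are conservative rather than an error.

Short-read junctions require canonical motifs, a maximum overhang of at
least 10 nt, and **more than** 5 uniquely mapped reads (6 is the first
passing value). Records without strand are dropped, since the canonical
check is strand-dependent. The long- and short-read sets are united on
the key (chrom, strand, intron start, intron end).

Filters are boolean and order-independent for the final set; the
rejection census reports reasons in the order mismatch filter, template
switch, non-canonical.

## TSS/TES calling

Internal-priming candidates are removed first: a 3' end is discarded when
more than 16 of the 20 genomic nucleotides downstream (transcription
direction, transcript sense: A on plus, T on minus) are adenines. The
window truncates at contig edges with the count taken over available
bases, so a short window can only under-call.

Per gene and end kind, with n total reads, t distinct observed end
positions and h reads at a candidate site, the binomial point mass
C(n,h)(1/t)^h(1−1/t)^(n−h) below α = 0.01 calls the site. Two details
were genuinely open and are resolved as follows:

* **Window-aggregated support (default).** End positions are stochastic
  around a dominant site, so testing the exact 1-bp position is blind to
  a real site whose support is spread by wobble: with 3'-end jitter of
  sd 10 nt, the modal position holds only ~4% of a gene's reads and never
  reaches significance at realistic coverage, pushing well-covered genes
  onto the fixed-window fallback — which then calls 2-read degradation
  clusters and destroys precision. The default therefore aggregates
  support within the attachment window (±10 nt TSS, ±30 nt TES) around
  each candidate and tests it two ways: (i) the exact-position point mass
  as printed above, and (ii) an enrichment test of the windowed support
  against the uniform-scatter null, where a random end falls inside the
  window with probability (2w+1)/span (span = range of observed
  positions), requiring the support to exceed its null expectation. The
  scatter null is only used when the gene shows scatter (t ≥ 10 distinct
  positions). Sites are claimed greedily, strongest first, and claimed
  observations support no further candidate, so the shoulder of a called
  peak cannot re-trigger. `window_support=False` restores the literal
  per-position test.
* **Point mass, not tail.** Clause (i) uses the point probability, not an
  upper-tail sum. The point mass is symmetric-tailed: a site holding far
  *fewer* reads than expected can also be "significant". This is kept
  deliberately in clause (i) — in the low-t regime (few distinct
  positions, e.g. two sharp alternative ends) it is exactly what lets the
  minority isoform be called alongside the majority one — while clause
  (ii) is one-sided because its job is to reject uniform degradation
  scatter.

t counts distinct observed positions with ≥ 1 read, not gene length: the
null is "reads distribute at random over the sites that exist". No
multiple-testing correction is applied within genes by default (raw 0.01);
a Bonferroni switch exists but is off.

Genes where no site of a kind reaches significance fall back to a greedy
sliding window: take the unclustered position with the highest support
(ties toward the transcription-direction 5'-most coordinate), gather all
observations within ±20 nt (TSS) / ±60 nt (TES), and emit a site at the
support-weighted modal position when the cluster holds ≥ 2 reads. A gene
qualifies for the high-confidence transcript path only with at least one
called TSS *and* one called TES (from either method); genes with fewer go
to the rescue partition, and their transcripts are carried forward
separately because transcript retention needs both ends.

## Collapse, filtering, wobble merge

Reads collapse at 1 bp resolution — identical intron chain *and* both end
coordinates — with gene loci assigned by transitive same-strand exonic
overlap (≥ 1 bp; intronic overlap does not group). Models are kept when
all junctions are in the HC set and the 5'/3' ends lie within 10/30 nt of
a called TSS/TES of their gene; models from rescue genes are kept apart
when their junctions are all HC; everything else is removed.

Wobble merging clusters transcripts with exactly identical intron chains
("m 0") whose 5' and 3' ends lie within 100 bp ("-a 100 -z 100"),
transitively; mono-exonic models must additionally overlap. Each cluster
emits one model at the member end coordinates carrying the highest summed
read support (ties toward the transcription-direction 5'-most
coordinate), with summed support. Because a cluster representative can
combine the 5' of one member with the 3' of another, a single pass of
transitive closure can leave two representatives that would themselves
merge; passes therefore repeat to a fixed point, which makes the
operation idempotent by construction and guarantees no residually
mergeable pair. Transitive chaining can join ends more than 100 nt apart
overall; this is accepted and matches the reference merge semantics.

Gene ids are `<prefix><chrom>G<10k>` ordered by span start per
chromosome, transcript suffixes `.k` by descending support — stable and
deterministic.

## Integration and final filters

Long- and short-read models "match" when their intron chains are
identical and both ends lie within 100 nt (the same criterion as the
initial wobble merge; mono-exonic models must overlap). Gene grouping for
the integration rules is recomputed jointly over both sources by
transitive exonic overlap, and retained models are relabelled with the
joint locus id (transcript ids — the abundance keys — are preserved), so
the downstream mono-exonic filter sees one gene per locus regardless of
source. Rules: (a) all long-read models with called ends are kept;
(b) a rescue model is re-admitted with ≥ 1 matching short-read model and
spliced length ≥ 0.8 × the mean spliced length of the gene's short-read
models — spliced length, not genomic span, since degradation shortens
transcripts, not introns; the mean is taken before any deduplication;
(c) short-read models are kept for loci without a retained long-read
model, or when they contribute ≥ 1 junction absent from the locus's
retained long-read junctions.

A mono-exonic gene (every transcript single-exon) is then removed when
its summed TPM exceeds 1 in fewer than 2 samples, unless some transcript
has an ORF longer than 100 amino acids (ORF lengths are consumed as
input; ORF calling is out of scope). An exclusion hook accepts a
user-supplied gene-id list (e.g. rRNA loci) since no automatic rRNA
detection is implemented. Finally, models with identical spliced
sense-strand sequences are deduplicated, keeping the first in
(gene id, transcript id) order.

## Motif profiles and benchmarks

±550 nt flanks around end sites are extracted sense-strand (sites whose
window crosses a contig edge are dropped from the site count), scanned
with DNA regular expressions counting **all** matches, overlapping
included, at their start position. The default patterns are
literature-standard consensi — TATA `TATA[AT]A[AT]`, Inr `[CT][CT]CA[CT][CT]`,
Y patch `[CT]{8,}`, Kozak `[AG][ACGT][ACGT]ATGG`, PAS `AATAAA`, CFIm
`TGTA` — and are configurable; they are stand-ins chosen by this package,
not an authoritative motif inventory. The random control draws the same
number of sites uniformly over the concatenated genome with random
strand. Dataset-to-dataset peak counts are compared with a two-sided
two-proportion chi-square test without continuity correction
(equivalently the two-proportion z-test).

Chimera counting marks a candidate transcript as chimeric when its
genomic span intersects ≥ 2 distinct full-length cDNA models by ≥ 1 bp on
the same strand; intersection is span-level, not exon-level, mirroring a
whole-feature interval intersection, and nested or duplicate cDNA
alignments count separately. Strandedness is this package's choice; an
unstranded variant would only increase counts.

Splicing-ratio validation: for each (primer pair, sample), a product's
RNA-seq ratio is the summed TPM of its transcripts over the summed TPM of
all the pair's products; pairs with zero total TPM in a sample are
dropped; Pearson and Spearman correlations are computed over all retained
(measured, RNA-seq) ratio pairs. The product-to-transcript mapping is
consumed as an explicit input table.

## The simulator

The generator emulates the data regime this pipeline targets, not
sequencing chemistry. Defaults (the study conditions used throughout the
tests): 200 genes on 2 chromosomes, 1–6 exons of 120–350 nt, introns
60–300 nt (all canonical GT-AG), GC 0.45, reads per gene log-uniform on
[5, 200], degradation probability 0.15 per end (≈ 0.3 of reads degraded,
with the cut point uniform over the transcript body), end jitter sd 3 nt
(5') / 10 nt (3'), and 5% rates each for junction shifts (1–10 nt
displacement plus a planted substitution within 10 nt of the false
junction), template switching (a planted canonical junction across an
8-mer direct repeat, Hamming distance 0), and internal priming (3' ends
terminating at a planted 18-of-20 A tract). 30% of multi-exon genes carry
an alternative TSS (120 nt downstream) and/or TES (150 nt upstream) at
35% isoform weight. A TATA consensus is planted so its profile position
is −30 from each primary TSS and an AATAAA at −20 from each TES. True
junctions whose flanks would accidentally trip the Hamming filter are
repaired at genome build time by mutating intron-interior bases. Half of
the mono-exonic genes are designated low expressors (> 1 TPM in exactly
one sample); other genes are guaranteed > 1 TPM in ≥ 2 samples so that
the expression filter removes exactly the designated set.

Reads are emitted directly as alignment records with correct CIGAR/MD;
the aligner is out of scope, so "mapping error" appears as junction
shifts with planted substitutions — precisely the failure mode the HC
junction filter targets. One seeded generator drives everything;
identical configuration yields byte-identical outputs.

**What passing tests do not show about real data:** base-call error
profiles, alignment ambiguity, fragment-length biology, expression-
dependent degradation, quantification noise beyond log-normal TPM, and
non-canonical real junctions are all absent. The simulation demonstrates
that the filtering logic does what it claims under its own model of the
artifacts — artifact detection rates on real libraries depend on how well
that model holds.

## Problem sizes and numerics

The test suite and acceptance script run 200-gene simulations
(~10,000 reads, ~500 true junctions), chosen as the smallest scale at
which all planted artifact classes appear in the hundreds; the wobble
property test uses 10,000 random models. The binomial mass is evaluated
through scipy's log-space implementation and agrees with exact rational
arithmetic to < 1e-12 over n ≤ 30, t ≤ 10 and normalises to 1 within
1e-12 up to n = 1000, t = 100. t = 1 is handled exactly (mass 1 at
h = n). Degenerate inputs: empty observation lists yield empty calls;
genes with a single read are never callable and land in rescue; zero-
noise simulation reconstructs every isoform observed at least twice,
exactly — isoforms sampled once are indistinguishable from fragments by
design.

## Known limitations

* The end caller's windowed enrichment clause assumes roughly uniform
  degradation scatter; strongly position-biased degradation could inflate
  its false-call rate.
* Wobble-merge representatives may chimerise the 5' of one member with
  the 3' of another (inherited from the reference semantics).
* rRNA removal, ORF calling, functional annotation and short-read
  assembly QC beyond the mono-exonic filter are out of scope; hooks
  consume their outputs.
* Only substitutions count as junction-window mismatches; if indels near
  junctions should also disqualify a read, clean-read counts here are
  upper bounds.
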