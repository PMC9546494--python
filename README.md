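# rtdforge

Tools for building a **reference transcript dataset (RTD)** — a curated
transcriptome suitable for alignment-free RNA-seq quantification — from
aligned full-length long reads (PacBio Iso-seq style FLNC reads) combined
with short-read splice-junction evidence and short-read transcript
assemblies.

Long-read transcriptomes are noisy in two specific ways: local sequence
errors near splice junctions cause mis-mapped intron boundaries ("edge
wander"), and mRNA degradation or incomplete cDNA synthesis produces
truncated reads whose 5'/3' ends are not real transcript start/end sites.
rtdforge implements the filtering logic that addresses both, plus the
merging and validation steps around it:

* **High-confidence splice junctions** (`sj_filter`): a junction is kept
  when it has a canonical donor/acceptor pair (GT-AG, GC-AG or AT-AC), at
  least one supporting read with zero substitutions within 10 nt of both
  intron boundaries, and no sign of reverse-transcriptase template
  switching — detected as a Hamming distance ≤ 1 between the 8-mer ending
  the upstream exon and the 8-mer ending the intron (or the mirrored
  comparison at the acceptor). Short-read junctions (STAR `SJ.out.tab`)
  qualify with canonical motifs, overhang ≥ 10 nt and > 5 unique reads.

* **TSS/TES calling** (`end_caller`): per gene, a candidate end site with
  *h* of *n* reads among *t* observed sites is scored with the binomial
  mass

  &nbsp;&nbsp;&nbsp;&nbsp;Pr(Reads = h) = C(n, h) (1/t)^h (1 − 1/t)^(n−h)

  and called when this probability falls below α = 0.01. Because real
  ends wobble around a dominant site, support is by default aggregated
  within the attachment window (±10 nt for TSS, ±30 nt for TES) and
  tested against a uniform-scatter null; genes where nothing reaches
  significance fall back to a sliding window (±20/±60 nt) requiring ≥ 2
  concordant reads. Putative internal-priming ends (> 16 A in the 20
  genomic nt downstream) are removed first.

* **Collapse, filter, wobble merge** (`collapse_merge`): reads collapse to
  transcript models at 1 bp resolution; models survive only if all their
  junctions are high-confidence and their ends lie within 10/30 nt of a
  called TSS/TES; finally transcripts with identical intron chains and
  ends within 100 bp merge to the most abundant end positions (TAMA merge
  "m 0 -a 100 -z 100" semantics).

* **Long/short-read integration** (`rtd_integrate`): long-read models with
  called ends are kept unconditionally; "rescue" models from genes without
  callable ends re-enter when a short-read model matches them and they
  reach 80% of the gene's mean short-read transcript length; short-read
  models survive for genes without long-read coverage or when they
  contribute novel junctions. Low-expressed mono-exonic genes
  (> 1 TPM in < 2 samples, no ORF > 100 aa) and duplicate spliced
  sequences are then removed.

* **Validation** (`motif_scan`, `evaluation`): positional density profiles
  of promoter/terminator motifs (TATA, Inr, Y patch, Kozak, PAS, CFIm) in
  ±550 nt flanks of called ends against random-site controls with a
  two-proportion test; chimeric-transcript counting against full-length
  cDNA mappings; splicing-ratio correlation against RT-PCR product
  proportions.

* **Simulation** (`simulate`): a seeded generator producing genomes with
  planted motifs, truth transcripts, FLNC-style read alignments with
  degradation/jitter/junction-shift/template-switch/internal-priming
  artifacts, short-read junction tables and TPM matrices — so the entire
  pipeline is testable without external data.

## Worked example

```bash
rtdforge simulate --seed 3 --n-genes 30 --outdir sim
rtdforge hcsj --sam sim/reads.sam --genome sim/genome.fa \
              --sj-tabs 'sim/sj.tab' --out hc_sj.tsv
rtdforge build --sam sim/reads.sam --genome sim/genome.fa \
               --sj-tabs 'sim/sj.tab' --out rtd.gtf --rescue-out rescue.bed
```

prints

```
wrote 1229 reads for 30 genes to sim
78 HC junctions (78 iso, 78 illumina)
42 transcripts written (42 long-read, 0 rescue)
```

The 30 simulated genes carry 78 true junctions, all recovered as
high-confidence by both evidence paths, and the 1229 reads (about a third
of them degraded, plus planted artifacts) collapse and filter down to 42
transcript models — the 30 primary isoforms plus the planted
alternative-end isoforms. `hc_sj.tsv` lists each junction with its clean
and total read support, e.g.

```
chrom  start  end   strand  source  clean_reads  total_reads
chr1   974    1227  +       both    19           19
```

The same steps are available as library calls (`rtdforge.pipeline.build_rtd`)
returning every intermediate: the HC junction sets, per-gene end calls and
the gene partition (binomial / fixed-window / rescue), the kept, rescue and
removed model sets, and the merged and integrated transcriptomes.

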