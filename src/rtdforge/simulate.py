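"""Synthetic genomes, transcript truths and full-length-read alignments.

The generator emulates the data this pipeline is built for: full-length
long reads from multi-exon genes with canonical GT-AG introns, a TATA
consensus planted 30 nt upstream of each primary TSS and an AATAAA
polyadenylation signal 20 nt upstream of each TES.  Reads suffer the
failure modes the filters target:

* 5'/3' degradation — read ends move uniformly into the transcript body;
* stochastic end wobble — integer Gaussian jitter on intact ends;
* junction shift — a splice boundary displaced 1-10 nt with a planted
  substitution within 10 nt of the false junction (the signature of
  mis-mapping caused by local sequence errors);
* template switching — a spurious junction across a planted 8-mer direct
  repeat (Hamming distance 0 between intron and exon flank);
* internal priming — the read 3' end terminates at a planted genomic
  A-tract (18 A in 20 nt) inside the transcript.

Short-read junction tables give every true junction > 5 unique reads and
>= 10 nt overhang (configurable dropout) and every planted-false junction
at most 5 reads.  The TPM matrix is log-normal per transcript x sample,
with designated mono-exonic low expressors (> 1 TPM in < 2 samples) for
the final filtering stage.  Reads are emitted directly as alignment
records (mapping itself is out of scope), so every stage of the pipeline
is testable against the recorded truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import GenomeSequence, ReadAlignment, SJTabRecord, TranscriptModel, reverse_complement
from .sj_filter import template_switch_test, make_junction

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study conditions for the simulator; one seed drives everything."""

    seed: int = 42
    n_genes: int = 200
    n_chromosomes: int = 2
    exons_per_gene: tuple[int, int] = (1, 6)
    exon_length: tuple[int, int] = (120, 350)
    intron_length: tuple[int, int] = (60, 300)
    gc_fraction: float = 0.45
    intergenic: int = 800
    reads_per_gene: tuple[int, int] = (5, 200)  # log-uniform
    truncation_prob_5: float = 0.15
    truncation_prob_3: float = 0.15
    tss_jitter_sd: float = 3.0
    tes_jitter_sd: float = 10.0
    junction_shift_rate: float = 0.05
    template_switch_rate: float = 0.05
    internal_priming_rate: float = 0.05
    alt_end_fraction: float = 0.3
    alt_tss_offset: int = 120
    alt_tes_offset: int = 150
    tata_offset: int = -30  # profile position of the planted TATA motif
    pas_offset: int = -20  # profile position of the planted PAS motif
    n_samples: int = 5
    sj_dropout: float = 0.0
    low_expressor_fraction: float = 0.5  # of mono-exonic genes

    def __post_init__(self):
        for rate in (
            self.truncation_prob_5,
            self.truncation_prob_3,
            self.junction_shift_rate,
            self.template_switch_rate,
            self.internal_priming_rate,
            self.alt_end_fraction,
            self.sj_dropout,
            self.low_expressor_fraction,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.intron_length[0] < 60:
            raise ValueError("minimum intron length must be >= 60")


@dataclass
class GeneTruth:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel]
    weights: list[float]
    tss: list[tuple[int, float]]  # (position, weight)
    tes: list[tuple[int, float]]
    ip_decoy: Optional[int] = None  # genomic 3' boundary of internal-priming stop
    ts_decoy: Optional[tuple[int, int]] = None  # spurious intron interval
    mono: bool = False
    low_expressor: bool = False

    @property
    def true_junctions(self) -> set:
        keys = set()
        for t in self.transcripts:
            keys.update(t.sj_keys())
        return keys


@dataclass
class ReadTruth:
    transcript_id: str
    labels: frozenset


@dataclass
class TruthTable:
    genes: dict[str, GeneTruth] = field(default_factory=dict)
    reads: dict[str, ReadTruth] = field(default_factory=dict)
    false_junctions: set = field(default_factory=set)
    orf_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def transcripts(self) -> list[TranscriptModel]:
        return [t for g in self.genes.values() for t in g.transcripts]

    @property
    def true_junctions(self) -> set:
        keys = set()
        for g in self.genes.values():
            keys |= g.true_junctions
        return keys


# ---------------------------------------------------------------------------
# Genome construction


def _write_sense(arr: np.ndarray, start: int, end: int, strand: str, seq: str) -> None:
    """Write ``seq`` so that the sense-strand reading of [start, end) is seq."""
    if strand == "-":
        seq = reverse_complement(seq)
    arr[start:end] = np.frombuffer(seq.encode(), dtype=np.uint8)


def _plant_at_offset(arr, anchor: int, strand: str, motif: str, offset: int) -> None:
    """Plant ``motif`` so a sense-strand flank profile anchored at ``anchor``
    shows a match starting at profile position ``offset``."""
    n = len(motif)
    if strand == "+":
        _write_sense(arr, anchor + offset, anchor + offset + n, "+", motif)
    else:
        _write_sense(arr, anchor - offset - n + 1, anchor - offset + 1, "-", motif)


def _random_seq(rng, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _canonicalize_intron(arr, start: int, end: int, strand: str) -> None:
    _write_sense(arr, start, start + 2, strand, "GT" if strand == "+" else "AG")
    _write_sense(arr, end - 2, end, strand, "AG" if strand == "+" else "GT")


def simulate_genome(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[GenomeSequence, TruthTable]:
    """Build a genome and its truth transcript models.

    Genes are placed non-overlapping on random strands; all true introns
    are canonical GT-AG; promoter/PAS motifs, internal-priming A-tracts
    and template-switch direct repeats are planted as documented above.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    layouts: dict[str, list] = {c: [] for c in chrom_names}
    cursors = {c: 0 for c in chrom_names}

    gene_specs = []
    for g in range(config.n_genes):
        chrom = chrom_names[g % config.n_chromosomes]
        strand = "+" if rng.random() < 0.5 else "-"
        k = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = [
            int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            for _ in range(k)
        ]
        intron_lens = [
            int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
            for _ in range(k - 1)
        ]
        alt_kind = None
        if k >= 2 and rng.random() < config.alt_end_fraction:
            alt_kind = ("tss", "tes", "both")[int(rng.integers(0, 3))]
        # guarantee room for alternative ends and planted features
        first_idx, last_idx = (0, k - 1) if strand == "+" else (k - 1, 0)
        if alt_kind in ("tss", "both"):
            exon_lens[first_idx] = max(exon_lens[first_idx], config.alt_tss_offset + 80)
        if alt_kind in ("tes", "both"):
            exon_lens[last_idx] = max(exon_lens[last_idx], config.alt_tes_offset + 80)
        if config.internal_priming_rate > 0:
            exon_lens[last_idx] = max(exon_lens[last_idx], 300)
        gene_specs.append((chrom, strand, exon_lens, intron_lens, alt_kind))

    truth = TruthTable()
    placed = []  # (gene index, chrom, strand, blocks, alt_kind)
    for g, (chrom, strand, exon_lens, intron_lens, alt_kind) in enumerate(gene_specs):
        start = cursors[chrom] + config.intergenic
        blocks = []
        pos = start
        for i, el in enumerate(exon_lens):
            blocks.append((pos, pos + el))
            pos += el
            if i < len(intron_lens):
                pos += intron_lens[i]
        cursors[chrom] = pos
        placed.append((g, chrom, strand, tuple(blocks), alt_kind))

    arrays = {
        c: _random_seq(rng, cursors[c] + config.intergenic, config.gc_fraction)
        for c in chrom_names
    }

    for g, chrom, strand, blocks, alt_kind in placed:
        arr = arrays[chrom]
        gene_id = f"SIMG{g + 1:04d}"
        k = len(blocks)
        mono = k == 1
        introns = [(blocks[i][1], blocks[i + 1][0]) for i in range(k - 1)]
        for istart, iend in introns:
            _canonicalize_intron(arr, istart, iend, strand)

        # transcript structures: primary plus optional alternative-end isoforms
        def clip5(bl, offset):
            if strand == "+":
                return ((bl[0][0] + offset, bl[0][1]),) + bl[1:]
            return bl[:-1] + ((bl[-1][0], bl[-1][1] - offset),)

        def clip3(bl, offset):
            if strand == "+":
                return bl[:-1] + ((bl[-1][0], bl[-1][1] - offset),)
            return ((bl[0][0] + offset, bl[0][1]),) + bl[1:]

        structures = [blocks]
        if alt_kind in ("tss", "both"):
            structures.append(clip5(blocks, config.alt_tss_offset))
        if alt_kind in ("tes", "both"):
            structures.append(clip3(blocks, config.alt_tes_offset))
        if alt_kind == "both":
            weights = [0.5] + [0.25] * (len(structures) - 1)
        elif alt_kind:
            weights = [0.65, 0.35]
        else:
            weights = [1.0]

        transcripts = [
            TranscriptModel(
                transcript_id=f"{gene_id}.{i + 1}",
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                exon_blocks=bl,
                source="isoseq",
            )
            for i, bl in enumerate(structures)
        ]

        tss: dict[int, float] = {}
        tes: dict[int, float] = {}
        for t, w in zip(transcripts, weights):
            tss[t.five_prime] = tss.get(t.five_prime, 0.0) + w
            tes[t.three_prime] = tes.get(t.three_prime, 0.0) + w

        _plant_at_offset(arr, transcripts[0].five_prime, strand, "TATAAAA", config.tata_offset)
        for pos in tes:
            _plant_at_offset(arr, pos, strand, "AATAAA", config.pas_offset)

        # internal-priming decoy: A-tract in the 5' half of the 3'-most exon,
        # well clear of the true (and alternative) TES positions
        ip_decoy = None
        if config.internal_priming_rate > 0:
            last = blocks[-1] if strand == "+" else blocks[0]
            if last[1] - last[0] >= 280:
                q = last[0] + 80 if strand == "+" else last[1] - 80
                ip_decoy = q  # read 3' boundary; tract lies just downstream
                tract = "A" * 9 + "C" + "A" * 9 + "C"  # 18 A in 20 nt
                if strand == "+":
                    _write_sense(arr, q, q + 20, "+", tract)
                else:
                    _write_sense(arr, q - 20, q, "-", tract)

        # template-switch decoy: spurious canonical junction across a
        # planted direct repeat inside the 5'-most exon
        ts_decoy = None
        if config.template_switch_rate > 0 and not mono:
            host = blocks[0] if strand == "+" else blocks[-1]
            if host[1] - host[0] >= 200:
                gap = 80
                if strand == "+":
                    d = host[0] + 40
                    a = d + gap
                    _write_sense(arr, d, d + 2, "+", "GT")
                    _write_sense(arr, a - 2, a, "+", "AG")
                    arr[a : a + 8] = arr[d : d + 8].copy()
                    ts_decoy = (d, a)
                else:
                    d = host[1] - 40
                    a = d - gap
                    _write_sense(arr, d - 2, d, "-", "GT")
                    _write_sense(arr, a, a + 2, "-", "AG")
                    arr[a - 8 : a] = arr[d - 8 : d].copy()
                    ts_decoy = (a, d)

        truth.genes[gene_id] = GeneTruth(
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            transcripts=transcripts,
            weights=weights,
            tss=sorted(tss.items()),
            tes=sorted(tes.items()),
            ip_decoy=ip_decoy,
            ts_decoy=ts_decoy,
            mono=mono,
            low_expressor=mono and rng.random() < config.low_expressor_fraction,
        )

        for t in transcripts:
            truth.orf_lengths[t.transcript_id] = (
                (150 if truth.genes[gene_id].low_expressor and rng.random() < 0.5 else 60)
                if mono
                else 200
            )

    # Repair true junctions that would accidentally trip the template-switch
    # Hamming filter: mutate intron-interior bases (never donor/acceptor
    # dinucleotides) until both comparisons have distance > 1.
    for _ in range(20):
        genome = GenomeSequence(
            {c: arrays[c].tobytes().decode("ascii") for c in chrom_names}
        )
        clean = True
        for gene in truth.genes.values():
            for chrom, strand, istart, iend in gene.true_junctions:
                j = make_junction(chrom, strand, istart, iend, genome)
                hd_d, hd_a, flagged = template_switch_test(j, genome)
                if not flagged:
                    continue
                clean = False
                arr = arrays[chrom]
                # rotate a base in the offending intron-side 8-mer interior
                if hd_d <= 1:
                    pos = iend - 5 if strand == "+" else istart + 4
                else:
                    pos = istart + 4 if strand == "+" else iend - 5
                arr[pos] = _BASES[(int(np.where(_BASES == arr[pos])[0][0]) + 1) % 4]
        if clean:
            break
    return genome, truth


# ---------------------------------------------------------------------------
# Reads


def _trim_left(blocks, cut: int):
    out = []
    remaining = cut
    for s, e in blocks:
        if remaining >= e - s:
            remaining -= e - s
            continue
        out.append((s + remaining, e))
        remaining = 0
    return tuple(out)


def _trim_right(blocks, cut: int):
    out = []
    remaining = cut
    for s, e in reversed(blocks):
        if remaining >= e - s:
            remaining -= e - s
            continue
        out.append((s, e - remaining))
        remaining = 0
    return tuple(reversed(out))


def _cut_at_boundary(blocks, q: int, keep: str):
    """Keep bases genomically left (< q) or right (>= q) of boundary q."""
    if keep == "left":
        return tuple((s, min(e, q)) for s, e in blocks if s < q)
    return tuple((max(s, q), e) for s, e in blocks if e > q)


def simulate_flnc_reads(
    genome: GenomeSequence,
    truth: TruthTable,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[ReadAlignment]:
    """Emit per-gene read alignments with artifact labels recorded in
    ``truth.reads`` and planted-false junctions in ``truth.false_junctions``.

    With every rate and jitter at zero, each read is an exact copy of its
    source transcript.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.reads_per_gene
    reads: list[ReadAlignment] = []
    for gene in truth.genes.values():
        n_reads = max(1, int(round(math.exp(rng.uniform(math.log(lo), math.log(hi))))))
        for i in range(n_reads):
            t_idx = int(rng.choice(len(gene.transcripts), p=np.array(gene.weights)))
            transcript = gene.transcripts[t_idx]
            blocks = transcript.exon_blocks
            strand = gene.strand
            labels = set()
            mismatches: list[int] = []

            if gene.ts_decoy is not None and rng.random() < config.template_switch_rate:
                d0, d1 = gene.ts_decoy
                host = [
                    bi
                    for bi, (s, e) in enumerate(blocks)
                    if s < d0 and d1 < e
                ]
                if host:
                    bi = host[0]
                    s, e = blocks[bi]
                    blocks = blocks[:bi] + ((s, d0), (d1, e)) + blocks[bi + 1 :]
                    labels.add("template_switch")
                    truth.false_junctions.add((gene.chrom, strand, d0, d1))

            internal_primed = False
            if gene.ip_decoy is not None and rng.random() < config.internal_priming_rate:
                keep = "left" if strand == "+" else "right"
                cut = _cut_at_boundary(blocks, gene.ip_decoy, keep)
                if cut and sum(e - s for s, e in cut) >= 50:
                    blocks = cut
                    labels.add("internal_priming")
                    internal_primed = True

            spliced = sum(e - s for s, e in blocks)
            if rng.random() < config.truncation_prob_5 and spliced > 120:
                cut = int(rng.integers(20, spliced - 80))
                blocks = _trim_left(blocks, cut) if strand == "+" else _trim_right(blocks, cut)
                labels.add("degraded5")
            spliced = sum(e - s for s, e in blocks)
            if (
                not internal_primed
                and rng.random() < config.truncation_prob_3
                and spliced > 120
            ):
                cut = int(rng.integers(20, spliced - 80))
                blocks = _trim_right(blocks, cut) if strand == "+" else _trim_left(blocks, cut)
                labels.add("degraded3")

            blocks = list(blocks)
            # stochastic wobble on intact ends
            if "degraded5" not in labels and config.tss_jitter_sd > 0:
                shift = int(round(rng.normal(0, config.tss_jitter_sd)))
                if strand == "+":
                    s, e = blocks[0]
                    blocks[0] = (min(max(0, s + shift), e - 20), e)
                else:
                    s, e = blocks[-1]
                    hi_bound = genome.length(gene.chrom)
                    blocks[-1] = (s, max(min(hi_bound, e + shift), s + 20))
            if (
                "degraded3" not in labels
                and not internal_primed
                and config.tes_jitter_sd > 0
            ):
                shift = int(round(rng.normal(0, config.tes_jitter_sd)))
                if strand == "+":
                    s, e = blocks[-1]
                    hi_bound = genome.length(gene.chrom)
                    blocks[-1] = (s, max(min(hi_bound, e + shift), s + 20))
                else:
                    s, e = blocks[0]
                    blocks[0] = (min(max(0, s + shift), e - 20), e)

            if len(blocks) >= 2 and rng.random() < config.junction_shift_rate:
                candidates = [
                    j for j in range(len(blocks) - 1) if blocks[j][1] - blocks[j][0] > 15
                ]
                if candidates:
                    j = candidates[int(rng.integers(0, len(candidates)))]
                    delta = int(rng.integers(1, 11))
                    s, e = blocks[j]
                    blocks[j] = (s, e - delta)
                    mismatches.append(e - delta - 1)
                    labels.add("junction_shift")
                    truth.false_junctions.add(
                        (gene.chrom, strand, e - delta, blocks[j + 1][0])
                    )

            read_id = f"{gene.gene_id}.r{i + 1}"
            reads.append(
                ReadAlignment(
                    read_id=read_id,
                    chrom=gene.chrom,
                    strand=strand,
                    exon_blocks=tuple(blocks),
                    mismatch_positions=tuple(mismatches),
                )
            )
            truth.reads[read_id] = ReadTruth(
                transcript_id=transcript.transcript_id, labels=frozenset(labels)
            )
    return reads


# ---------------------------------------------------------------------------
# Short-read junction tables and abundances


def simulate_sj_tab(
    truth: TruthTable,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[SJTabRecord]:
    """True junctions receive > 5 unique reads and >= 10 nt overhang
    (subject to ``sj_dropout``); planted-false junctions at most 5 reads."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    records = []
    for chrom, strand, start, end in sorted(truth.true_junctions):
        if rng.random() < config.sj_dropout:
            continue
        records.append(
            SJTabRecord(
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                motif_code=0,
                unique_reads=int(rng.integers(6, 61)),
                max_overhang=int(rng.integers(10, 51)),
            )
        )
    for chrom, strand, start, end in sorted(truth.false_junctions):
        records.append(
            SJTabRecord(
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                motif_code=0,
                unique_reads=int(rng.integers(0, 6)),
                max_overhang=int(rng.integers(5, 31)),
            )
        )
    return records


def simulate_tpm(
    truth: TruthTable,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Log-normal transcript x sample TPM.  Designated mono-exonic low
    expressors exceed 1 TPM in exactly one sample; every other gene is
    guaranteed > 1 TPM in at least two samples."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    samples = [f"S{i + 1}" for i in range(config.n_samples)]
    rows = {}
    for gene in truth.genes.values():
        tids = [t.transcript_id for t in gene.transcripts]
        if gene.low_expressor:
            hot = int(rng.integers(0, config.n_samples))
            for tid in tids:
                vals = np.full(config.n_samples, 0.05)
                vals[hot] = 3.0
                rows[tid] = vals
        else:
            for tid in tids:
                rows[tid] = rng.lognormal(mean=1.0, sigma=1.0, size=config.n_samples)
            gene_sum = np.sum([rows[t] for t in tids], axis=0)
            if int((gene_sum > 1.0).sum()) < 2:
                order = np.argsort(gene_sum)[::-1]
                for s in order[:2]:
                    rows[tids[0]][s] = max(rows[tids[0]][s], 2.0)
    return pd.DataFrame(rows, index=samples).T


# ---------------------------------------------------------------------------
# One-call dataset


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: GenomeSequence
    truth: TruthTable
    reads: list[ReadAlignment]
    sj_records: list[SJTabRecord]
    tpm: pd.DataFrame


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate every pipeline input from a single seeded generator."""
    rng = np.random.default_rng(config.seed)
    genome, truth = simulate_genome(config, rng)
    reads = simulate_flnc_reads(genome, truth, config, rng)
    sj_records = simulate_sj_tab(truth, config, rng)
    tpm = simulate_tpm(truth, config, rng)
    return SimulatedDataset(
        config=config,
        genome=genome,
        truth=truth,
        reads=reads,
        sj_records=sj_records,
        tpm=tpm,
    )


def write_dataset(dataset: SimulatedDataset, outdir) -> None:
    """Write genome.fa, reads.sam, truth.bed, truth_ends.tsv, sj.tab,
    tpm.tsv and orfs.tsv under ``outdir``."""
    from pathlib import Path

    from . import io_formats

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io_formats.write_genome_fasta(dataset.genome, outdir / "genome.fa")
    io_formats.write_alignments_sam(dataset.reads, dataset.genome, outdir / "reads.sam")
    io_formats.write_bed12(dataset.truth.transcripts, outdir / "truth.bed")
    io_formats.write_sj_tab(dataset.sj_records, outdir / "sj.tab")
    io_formats.write_tpm_table(dataset.tpm, outdir / "tpm.tsv")
    io_formats.write_orf_table(dataset.truth.orf_lengths, outdir / "orfs.tsv")
    with open(outdir / "truth_ends.tsv", "w") as fh:
        fh.write("gene_id\tkind\tposition\tweight\n")
        for gene in dataset.truth.genes.values():
            for pos, w in gene.tss:
                fh.write(f"{gene.gene_id}\tTSS\t{pos}\t{w}\n")
            for pos, w in gene.tes:
                fh.write(f"{gene.gene_id}\tTES\t{pos}\t{w}\n")
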