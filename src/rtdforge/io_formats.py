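"""Readers and writers for the external formats the pipeline touches.

One coordinate convention rules the package: 0-based half-open, genomic
(leftmost-first) block order.  All conversions from 1-based closed formats
(GTF, STAR SJ tab) happen here and only here.

Supported formats: FASTA, SAM (CIGAR + optional MD), BED12 in the TAMA
name dialect (``gene_id;transcript_id``), GTF2.2 exon features, 9-column
STAR ``SJ.out.tab``, TSV abundance (transcript x sample TPM) and ORF-length
tables, and the RT-PCR product proportion table used for validation.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam
from Bio import SeqIO

from .core import (
    GenomeSequence,
    ReadAlignment,
    SJTabRecord,
    TranscriptModel,
)

# ---------------------------------------------------------------------------
# FASTA


def read_genome_fasta(path) -> GenomeSequence:
    """Load a FASTA file into a :class:`GenomeSequence` (uppercased)."""
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValueError(f"duplicate contig name: {record.id!r}")
        seqs[record.id] = str(record.seq)
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSequence(seqs)


def write_genome_fasta(genome: GenomeSequence, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# SAM

_CIGAR_REF_CONSUMING = {0, 2, 3, 7, 8}  # M, D, N, =, X
_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


def blocks_from_cigar(reference_start: int, cigartuples) -> tuple[tuple[int, int], ...]:
    """Exon blocks implied by a CIGAR: N gaps split blocks, M/=/X/D extend them."""
    blocks = []
    pos = reference_start
    block_start = pos
    consumed = False
    for op, length in cigartuples:
        if op == 3:  # N: intron
            if not consumed:
                raise ValueError("CIGAR starts with N or has empty block")
            blocks.append((block_start, pos))
            pos += length
            block_start = pos
            consumed = False
        elif op in (0, 2, 7, 8):  # M, D, =, X
            pos += length
            consumed = True
        # I, S, H, P consume no reference
    if not consumed:
        raise ValueError("CIGAR ends with N or has empty block")
    blocks.append((block_start, pos))
    return tuple(blocks)


def mismatches_from_md(reference_start: int, cigartuples, md: str) -> tuple[int, ...]:
    """Genomic positions of substitutions recovered from an MD tag.

    Deletions (``^ACGT`` runs in MD, D ops in CIGAR) are consumed but not
    reported; only substitutions count.
    """
    # Walk of reference-consuming, MD-visible bases: (genomic pos, is_deletion)
    walk: list[tuple[int, bool]] = []
    pos = reference_start
    for op, length in cigartuples:
        if op in (0, 7, 8):
            walk.extend((pos + i, False) for i in range(length))
            pos += length
        elif op == 2:
            walk.extend((pos + i, True) for i in range(length))
            pos += length
        elif op == 3:
            pos += length
    out = []
    i = 0
    for m in _MD_TOKEN.finditer(md):
        num, deletion, sub = m.groups()
        if num is not None:
            i += int(num)
        elif deletion is not None:
            for _ in deletion[1:]:
                if i >= len(walk) or not walk[i][1]:
                    raise ValueError(f"MD deletion inconsistent with CIGAR: {md!r}")
                i += 1
        else:
            if i >= len(walk):
                raise ValueError(f"MD tag longer than aligned reference: {md!r}")
            gpos, is_del = walk[i]
            if is_del:
                raise ValueError(f"MD substitution inside CIGAR deletion: {md!r}")
            out.append(gpos)
            i += 1
    if i != len(walk):
        raise ValueError(f"MD tag covers {i} of {len(walk)} aligned bases: {md!r}")
    return tuple(out)


def _mismatches_by_comparison(aln, genome: GenomeSequence) -> tuple[int, ...]:
    """Substitution positions by direct base comparison against the genome."""
    query = aln.query_sequence
    if query is None:
        raise ValueError(f"read {aln.query_name}: no SEQ and no MD tag")
    ref = genome[aln.reference_name]
    out = []
    qpos = 0
    rpos = aln.reference_start
    for op, length in aln.cigartuples:
        if op in (0, 7, 8):
            for i in range(length):
                if query[qpos + i].upper() != ref[rpos + i]:
                    out.append(rpos + i)
            qpos += length
            rpos += length
        elif op in (1, 4):  # I, S
            qpos += length
        elif op in (2, 3):  # D, N
            rpos += length
    return tuple(out)


def read_alignments_sam(path, genome: Optional[GenomeSequence] = None) -> list[ReadAlignment]:
    """Digest a SAM/BAM file into :class:`ReadAlignment` records.

    Unmapped and secondary records are skipped; supplementary alignments
    are kept but flagged.  Substitution positions come from the MD tag
    when present, else from base comparison against ``genome``.
    """
    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary:
                continue
            if genome is not None and aln.reference_name not in genome:
                raise ValueError(f"reference {aln.reference_name!r} absent from genome")
            blocks = blocks_from_cigar(aln.reference_start, aln.cigartuples)
            if aln.has_tag("MD"):
                mism = mismatches_from_md(
                    aln.reference_start, aln.cigartuples, aln.get_tag("MD")
                )
            elif genome is not None:
                mism = _mismatches_by_comparison(aln, genome)
            else:
                raise ValueError(
                    f"read {aln.query_name}: no MD tag and no genome for "
                    "mismatch recovery"
                )
            out.append(
                ReadAlignment(
                    read_id=aln.query_name,
                    chrom=aln.reference_name,
                    strand="-" if aln.is_reverse else "+",
                    exon_blocks=blocks,
                    mismatch_positions=mism,
                    is_supplementary=aln.is_supplementary,
                )
            )
    return out


_SUBSTITUTE = {"A": "C", "C": "A", "G": "T", "T": "G", "N": "A"}


def write_alignments_sam(alignments: Sequence[ReadAlignment], genome: GenomeSequence, path) -> None:
    """Emit alignments as SAM with correct CIGAR, SEQ, MD and NM.

    Read sequences are reconstructed from the genome; each recorded
    mismatch position carries a deterministic substituted base, so a
    round-trip through :func:`read_alignments_sam` is the identity.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name in genome:
            fh.write(f"@SQ\tSN:{name}\tLN:{genome.length(name)}\n")
        for aln in alignments:
            mism = set(aln.mismatch_positions)
            seq_parts = []
            md_parts = []
            run = 0
            for bs, be in aln.exon_blocks:
                ref = genome.fetch(aln.chrom, bs, be)
                bases = list(ref)
                for i, base in enumerate(bases):
                    gpos = bs + i
                    if gpos in mism:
                        md_parts.append(str(run))
                        md_parts.append(base)  # MD stores the reference base
                        run = 0
                        bases[i] = _SUBSTITUTE[base]
                    else:
                        run += 1
                seq_parts.append("".join(bases))
            md_parts.append(str(run))
            cigar = []
            for i, (bs, be) in enumerate(aln.exon_blocks):
                if i:
                    cigar.append(f"{bs - aln.exon_blocks[i - 1][1]}N")
                cigar.append(f"{be - bs}M")
            flag = (16 if aln.strand == "-" else 0) | (2048 if aln.is_supplementary else 0)
            seq = "".join(seq_parts)
            fh.write(
                "\t".join(
                    [
                        aln.read_id,
                        str(flag),
                        aln.chrom,
                        str(aln.start + 1),
                        "60",
                        "".join(cigar),
                        "*",
                        "0",
                        "0",
                        seq,
                        "*",
                        f"NM:i:{len(mism)}",
                        "MD:Z:" + "".join(md_parts),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED12 (TAMA name dialect: "gene_id;transcript_id")


def read_bed12(path, source: str = "isoseq") -> list[TranscriptModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED columns")
            chrom, cs, ce, name, score, strand = fields[:6]
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            chrom_start, chrom_end = int(cs), int(ce)
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{path}:{lineno}: block count mismatch")
            blocks = tuple(
                (chrom_start + st, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            )
            if starts[0] != 0 or blocks[-1][1] != chrom_end:
                raise ValueError(f"{path}:{lineno}: blocks inconsistent with span")
            if ";" in name:
                gene_id, transcript_id = name.split(";", 1)
            else:
                gene_id = transcript_id = name
            try:
                support = int(score)
            except ValueError:
                support = 1
            models.append(
                TranscriptModel(
                    transcript_id=transcript_id,
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    exon_blocks=blocks,
                    source=source,
                    read_support=support,
                )
            )
    return models


def write_bed12(models: Iterable[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for m in models:
            sizes = ",".join(str(e - s) for s, e in m.exon_blocks)
            starts = ",".join(str(s - m.start) for s, e in m.exon_blocks)
            fh.write(
                "\t".join(
                    [
                        m.chrom,
                        str(m.start),
                        str(m.end),
                        f"{m.gene_id};{m.transcript_id}",
                        str(m.read_support),
                        m.strand,
                        str(m.start),
                        str(m.end),
                        "0",
                        str(len(m.exon_blocks)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GTF (exon features only; 1-based closed on disk)

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path, source: str = "illumina") -> list[TranscriptModel]:
    """Parse exon features into transcript models (CDS and others ignored)."""
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "exon":
                continue
            chrom, src, _, start, end, _, strand = fields[:7]
            attrs = dict(_GTF_ATTR.findall(fields[8]))
            tid = attrs.get("transcript_id")
            gid = attrs.get("gene_id", tid)
            if tid is None:
                raise ValueError(f"exon feature without transcript_id in {path}")
            exons.setdefault(tid, []).append((int(start) - 1, int(end)))
            src_label = src if src in ("isoseq", "illumina") else source
            meta[tid] = (gid, chrom, strand, src_label)
    models = []
    for tid, blocks in exons.items():
        gid, chrom, strand, src_label = meta[tid]
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                exon_blocks=tuple(sorted(blocks)),
                source=src_label,
                read_support=1,
            )
        )
    return models


def write_gtf(models: Iterable[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            for s, e in m.exon_blocks:
                fh.write(
                    "\t".join(
                        [m.chrom, m.source, "exon", str(s + 1), str(e), ".",
                         m.strand, ".", attrs]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# STAR SJ.out.tab (9 columns, 1-based closed intron on disk)

_SJ_STRAND = {0: None, 1: "+", 2: "-"}


def read_sj_tab(path) -> list[SJTabRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            chrom = fields[0]
            start_1based, end_1based = int(fields[1]), int(fields[2])
            strand_code, motif = int(fields[3]), int(fields[4])
            unique, overhang = int(fields[6]), int(fields[8])
            if strand_code not in _SJ_STRAND:
                raise ValueError(f"{path}:{lineno}: bad strand code {strand_code}")
            records.append(
                SJTabRecord(
                    chrom=chrom,
                    start=start_1based - 1,
                    end=end_1based,
                    strand=_SJ_STRAND[strand_code],
                    motif_code=motif,
                    unique_reads=unique,
                    max_overhang=overhang,
                )
            )
    return records


def write_sj_tab(records: Iterable[SJTabRecord], path) -> None:
    code = {None: 0, "+": 1, "-": 2}
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    [r.chrom, str(r.start + 1), str(r.end), str(code[r.strand]),
                     str(r.motif_code), "0", str(r.unique_reads), "0",
                     str(r.max_overhang)]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Tables


def read_tpm_table(path) -> pd.DataFrame:
    """TSV with transcript ids in the first column, one column per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"duplicate transcript ids in {path}")
    return df


def write_tpm_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="transcript_id")


def read_orf_table(path) -> dict[str, int]:
    """TSV of transcript_id -> ORF length in amino acids."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(int)))


def write_orf_table(orfs: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\torf_aa\n")
        for tid, aa in orfs.items():
            fh.write(f"{tid}\t{aa}\n")


def read_rtpcr_table(path):
    """RT-PCR product proportions: primer_pair, product, sample, proportion,
    transcript_ids (comma-separated)."""
    from .evaluation import RTPCRRecord  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            RTPCRRecord(
                primer_pair=str(row.primer_pair),
                product=str(row.product),
                sample=str(row.sample),
                proportion=float(row.proportion),
                transcript_ids=tuple(str(row.transcript_ids).split(",")),
            )
        )
    return records
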