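"""High-confidence splice-junction filtering.

Long-read junctions are kept when they have canonical splice dinucleotides,
at least one supporting read with no substitutions within 10 nt of either
intron boundary (on the exonic side), and no sign of reverse-transcriptase
template switching.  Template switching at short direct repeats is detected
by comparing the last 8 sense-strand bases of the upstream exon with the
last 8 bases of the intron, and the first 8 bases of the intron with the
first 8 bases of the downstream exon; a Hamming distance of 1 or less in
either comparison flags the junction.

Short-read junctions (STAR tab records) are kept when canonical, with a
maximum overhang of at least 10 nt and more than 5 uniquely mapped
supporting reads.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from .core import (
    GenomeSequence,
    ReadAlignment,
    SJEvidence,
    SJTabRecord,
    SpliceJunction,
    reverse_complement,
)

#: Spliceosomal donor/acceptor pairs accepted as canonical (sense strand).
CANONICAL_PAIRS = frozenset({("GT", "AG"), ("GC", "AG"), ("AT", "AC")})

MISMATCH_WINDOW = 10  # nt of exon flank scanned for substitutions
REPEAT_K = 8  # bases compared in the template-switch test


def make_junction(chrom: str, strand: str, start: int, end: int, genome: GenomeSequence) -> SpliceJunction:
    """Build a junction for intron [start, end), extracting sense-strand
    donor/acceptor dinucleotides (reverse-complemented on the minus strand)."""
    left = genome.fetch_padded(chrom, start, start + 2, pad="N")
    right = genome.fetch_padded(chrom, end - 2, end, pad="N")
    if strand == "+":
        donor, acceptor = left, right
    else:
        donor, acceptor = reverse_complement(right), reverse_complement(left)
    return SpliceJunction(chrom=chrom, strand=strand, start=start, end=end,
                          donor=donor, acceptor=acceptor)


def junctions_from_alignment(
    read: ReadAlignment, genome: GenomeSequence, window: int = MISMATCH_WINDOW
) -> list[tuple[SpliceJunction, int]]:
    """Junctions of one read with the count of its substitutions falling
    within ``window`` nt of either intron boundary, exonic side only.

    A read supports a junction "cleanly" when this count is zero at both
    boundaries, i.e. it is a perfect match within the window upstream and
    downstream of the junction.
    """
    out = []
    for start, end in read.introns:
        n = sum(
            1
            for p in read.mismatch_positions
            if start - window <= p < start or end <= p < end + window
        )
        out.append((make_junction(read.chrom, read.strand, start, end, genome), n))
    return out


def is_canonical(junction: SpliceJunction) -> bool:
    return (junction.donor, junction.acceptor) in CANONICAL_PAIRS


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b))


def template_switch_test(
    junction: SpliceJunction, genome: GenomeSequence, max_hd: int = 1
) -> tuple[int, int, bool]:
    """Hamming-distance test for RT template switching at direct repeats.

    Returns ``(hd_donor, hd_acceptor, flagged)`` where ``hd_donor`` compares
    the last 8 bases of the upstream exon with the last 8 bases of the
    intron and ``hd_acceptor`` compares the first 8 bases of the intron with
    the first 8 bases of the downstream exon (all sense strand).  Positions
    beyond a contig edge are padded with distinct sentinels and never match.
    """
    chrom, start, end = junction.chrom, junction.start, junction.end
    k = REPEAT_K
    if junction.strand == "+":
        exon_up = genome.fetch_padded(chrom, start - k, start, pad="<")
        intron_tail = genome.fetch_padded(chrom, end - k, end, pad=">")
        intron_head = genome.fetch_padded(chrom, start, start + k, pad=">")
        exon_down = genome.fetch_padded(chrom, end, end + k, pad="<")
    else:
        exon_up = reverse_complement(genome.fetch_padded(chrom, end, end + k, pad="<"))
        intron_tail = reverse_complement(genome.fetch_padded(chrom, start, start + k, pad=">"))
        intron_head = reverse_complement(genome.fetch_padded(chrom, end - k, end, pad=">"))
        exon_down = reverse_complement(genome.fetch_padded(chrom, start - k, start, pad="<"))
    hd_donor = hamming(exon_up, intron_tail)
    hd_acceptor = hamming(intron_head, exon_down)
    return hd_donor, hd_acceptor, min(hd_donor, hd_acceptor) <= max_hd


def collect_sj_evidence(
    alignments: Iterable[ReadAlignment],
    genome: GenomeSequence,
    window: int = MISMATCH_WINDOW,
) -> dict[tuple, SJEvidence]:
    """Aggregate per-junction evidence over a set of read alignments."""
    evidence: dict[tuple, SJEvidence] = {}
    for read in alignments:
        for junction, n_mismatch in junctions_from_alignment(read, genome, window):
            ev = evidence.get(junction.key)
            if ev is None:
                hd_d, hd_a, flagged = template_switch_test(junction, genome)
                ev = SJEvidence(
                    junction=junction,
                    template_switch=flagged,
                    hd_donor=hd_d,
                    hd_acceptor=hd_a,
                )
                evidence[junction.key] = ev
            ev.supporting_read_count += 1
            if n_mismatch == 0:
                ev.clean_read_count += 1
    return evidence


def hc_sj_longread(evidence: Iterable[SJEvidence]) -> set:
    """Long-read HC junction keys: canonical AND >= 1 clean supporting read
    AND not flagged as a template-switch artifact."""
    return {
        ev.junction.key
        for ev in evidence
        if is_canonical(ev.junction)
        and ev.clean_read_count >= 1
        and not ev.template_switch
    }


def classify_longread_rejections(evidence: Iterable[SJEvidence]) -> dict[str, int]:
    """Count rejected junctions by the first failing filter, applied in the
    order: mismatch filter, template switch, non-canonical motifs."""
    counts = {"hc": 0, "mismatch": 0, "template_switch": 0, "non_canonical": 0}
    for ev in evidence:
        if ev.clean_read_count < 1:
            counts["mismatch"] += 1
        elif ev.template_switch:
            counts["template_switch"] += 1
        elif not is_canonical(ev.junction):
            counts["non_canonical"] += 1
        else:
            counts["hc"] += 1
    return counts


def hc_sj_shortread(
    records: Iterable[SJTabRecord],
    genome: GenomeSequence,
    min_overhang: int = 10,
    min_unique: int = 6,
) -> set:
    """Short-read HC junction keys: canonical, overhang >= 10 nt, more than
    5 unique supporting reads.  Strand-undefined records are dropped."""
    out = set()
    for rec in records:
        if rec.strand is None:
            continue
        junction = make_junction(rec.chrom, rec.strand, rec.start, rec.end, genome)
        if (
            is_canonical(junction)
            and rec.max_overhang >= min_overhang
            and rec.unique_reads >= min_unique
        ):
            out.add(junction.key)
    return out


def union_hc(long_set: set, short_set: set) -> set:
    """Union of the long- and short-read HC sets, keyed by
    (chrom, strand, intron start, intron end)."""
    return set(long_set) | set(short_set)
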