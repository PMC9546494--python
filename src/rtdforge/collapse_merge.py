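"""Read collapsing, HC filtering and end-wobble merging of transcript models.

Reads are collapsed at 1 bp resolution: two reads produce the same model
only when their intron chains and both end coordinates are identical.
Collapsed models are filtered against the high-confidence feature set
(junctions all HC; 5' end within 10 nt of a called TSS and 3' end within
30 nt of a called TES of the gene).  Finally, wobble merging collapses
transcripts with identical intron chains whose 5' and 3' ends lie within
100 bp (transitively), keeping the most abundant end positions — the
"m 0 -a 100 -z 100" merge semantics of TAMA.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import replace
from typing import Iterable, Optional, Sequence

from .core import HCFeatureSet, Interval, ReadAlignment, TranscriptModel


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _group_exonic_overlap(items: Sequence) -> list[list[int]]:
    """Connected components under same-strand exonic overlap (>= 1 bp),
    by transitive closure.  ``items`` need chrom/strand/exon_blocks."""
    uf = _UnionFind(len(items))
    buckets: dict[tuple, list[tuple[int, int, int]]] = defaultdict(list)
    for idx, it in enumerate(items):
        for s, e in it.exon_blocks:
            buckets[(it.chrom, it.strand)].append((s, e, idx))
    for blocks in buckets.values():
        blocks.sort()
        active_end = -1
        active_idx = -1
        for s, e, idx in blocks:
            if s < active_end:
                uf.union(active_idx, idx)
                active_end = max(active_end, e)
            else:
                active_idx, active_end = idx, e
    comps: dict[int, list[int]] = defaultdict(list)
    for i in range(len(items)):
        comps[uf.find(i)].append(i)
    return list(comps.values())


def assign_gene_ids(
    models: Sequence[TranscriptModel], prefix: str = "RTD"
) -> list[TranscriptModel]:
    """Group models into gene loci by transitive same-strand exonic overlap
    and assign stable ids: genes ``<prefix><chrom>G<10,20,...>`` ordered by
    span start per chromosome, transcripts ``.1, .2, ...`` by descending
    read support (ties toward the 5'-most, then lexicographic id)."""
    comps = _group_exonic_overlap(models)
    comps.sort(key=lambda c: (models[c[0]].chrom, min(models[i].start for i in c)))
    counters: dict[str, int] = defaultdict(int)
    out: list[Optional[TranscriptModel]] = [None] * len(models)
    for comp in comps:
        chrom = models[comp[0]].chrom
        strand = models[comp[0]].strand
        counters[chrom] += 1
        gene_id = f"{prefix}{chrom}G{counters[chrom] * 10}"
        ranked = sorted(
            comp,
            key=lambda i: (
                -models[i].read_support,
                models[i].five_prime if strand == "+" else -models[i].five_prime,
                models[i].transcript_id,
            ),
        )
        for k, i in enumerate(ranked, 1):
            out[i] = models[i].with_ids(gene_id, f"{gene_id}.{k}")
    return [m for m in out if m is not None]


def collapse_reads(
    alignments: Iterable[ReadAlignment], prefix: str = "RTD"
) -> list[TranscriptModel]:
    """Collapse primary read alignments into transcript models at 1 bp
    resolution: identical (intron chain, start, end) tuples become one
    model whose ``read_support`` is the read count.  Gene loci are assigned
    by transitive exonic overlap per strand."""
    groups: dict[tuple, list[ReadAlignment]] = defaultdict(list)
    for read in alignments:
        if read.is_supplementary:
            continue
        key = (read.chrom, read.strand, read.exon_blocks)
        groups[key].append(read)
    models = []
    for (chrom, strand, blocks), reads in groups.items():
        models.append(
            TranscriptModel(
                transcript_id=reads[0].read_id,
                gene_id=reads[0].read_id,
                chrom=chrom,
                strand=strand,
                exon_blocks=blocks,
                source="isoseq",
                read_support=len(reads),
                read_ids=tuple(r.read_id for r in reads),
            )
        )
    return assign_gene_ids(models, prefix=prefix)


def filter_transcripts(
    models: Sequence[TranscriptModel],
    hc: HCFeatureSet,
    tss_window: int = 10,
    tes_window: int = 30,
) -> tuple[list[TranscriptModel], list[TranscriptModel], list[TranscriptModel]]:
    """Filter models against the HC feature set.

    ``kept``: all junctions HC and, for a gene with called TSS and TES,
    the 5' end within ``tss_window`` of a called TSS and the 3' end within
    ``tes_window`` of a called TES.  ``rescue``: models with all-HC
    junctions from genes lacking called ends (kept separately for
    conditional re-admission during integration).  ``removed``: the rest.
    """
    kept, rescue, removed = [], [], []
    for m in models:
        sj_ok = all(k in hc.hc_sj for k in m.sj_keys())
        if hc.gene_has_ends(m.gene_id):
            tss_ok = any(
                abs(m.five_prime - s.position) <= tss_window
                for s in hc.tss[m.gene_id]
            )
            tes_ok = any(
                abs(m.three_prime - s.position) <= tes_window
                for s in hc.tes[m.gene_id]
            )
            (kept if sj_ok and tss_ok and tes_ok else removed).append(m)
        else:
            (rescue if sj_ok else removed).append(m)
    return kept, rescue, removed


def _pick_end(members: Sequence[TranscriptModel], which: str, strand: str) -> int:
    """Most abundant end coordinate among cluster members; ties break toward
    the transcription-direction 5'-most coordinate."""
    support: dict[int, int] = defaultdict(int)
    for m in members:
        pos = m.five_prime if which == "five" else m.three_prime
        support[pos] += m.read_support
    return max(support, key=lambda p: (support[p], p if strand == "-" else -p))


def _merge_cluster(members: list[TranscriptModel], strand: str) -> TranscriptModel:
    rep = max(members, key=lambda m: (m.read_support, m.transcript_id))
    five = _pick_end(members, "five", strand)
    three = _pick_end(members, "three", strand)
    left, right = (five, three) if strand == "+" else (three, five)
    introns = rep.introns
    bounds = [left] + [c for s, e in introns for c in (s, e)] + [right]
    blocks = tuple((bounds[i], bounds[i + 1]) for i in range(0, len(bounds), 2))
    return replace(
        rep,
        exon_blocks=blocks,
        read_support=sum(m.read_support for m in members),
        read_ids=tuple(r for m in members for r in m.read_ids),
    )


def _wobble_pass(
    models: Sequence[TranscriptModel], w5: int, w3: int
) -> list[TranscriptModel]:
    groups: dict[tuple, list[int]] = defaultdict(list)
    for i, m in enumerate(models):
        groups[(m.chrom, m.strand, m.introns)].append(i)
    out = []
    for (chrom, strand, introns), idxs in groups.items():
        uf = _UnionFind(len(idxs))
        mono = not introns
        for a in range(len(idxs)):
            ma = models[idxs[a]]
            for b in range(a + 1, len(idxs)):
                mb = models[idxs[b]]
                close = (
                    abs(ma.five_prime - mb.five_prime) <= w5
                    and abs(ma.three_prime - mb.three_prime) <= w3
                )
                if mono:
                    close = close and ma.start < mb.end and mb.start < ma.end
                if close:
                    uf.union(a, b)
        comps: dict[int, list[TranscriptModel]] = defaultdict(list)
        for a, i in enumerate(idxs):
            comps[uf.find(a)].append(models[i])
        for members in comps.values():
            out.append(_merge_cluster(members, strand))
    return out


def wobble_merge(
    models: Sequence[TranscriptModel],
    sj_tolerance: int = 0,
    w5: int = 100,
    w3: int = 100,
) -> list[TranscriptModel]:
    """End-wobble merge with exact intron-chain matching.

    Transcripts cluster (transitively) when their intron chains are
    identical and both the 5' and 3' ends lie within ``w5``/``w3``;
    mono-exonic transcripts additionally require interval overlap.  Each
    cluster emits one model at the most abundant member 5' and 3' ends,
    with summed read support.  Passes repeat until a fixed point, so the
    operation is idempotent and leaves no residually mergeable pair.
    """
    if sj_tolerance != 0:
        raise NotImplementedError("only exact intron-chain matching (m 0) is supported")
    current = list(models)
    while True:
        merged = _wobble_pass(current, w5, w3)
        if len(merged) == len(current):
            return sorted(merged, key=lambda m: (m.chrom, m.start, m.end, m.transcript_id))
        current = merged
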