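"""Integration of long-read and short-read transcriptomes into one RTD.

Priority rules:

(a) every long-read model with high-confidence TSS/TES is kept;
(b) long-read models from genes lacking called ends (the rescue set) are
    re-admitted only when a short-read model matches them (identical
    intron chain, both ends within 100 nt) and their spliced length is at
    least 80% of the mean spliced length of the gene's short-read models;
(c) short-read models are retained for genes with no retained long-read
    model, or when they contribute at least one splice junction absent
    from the gene's retained long-read junctions.

Afterwards, mono-exonic genes expressed above 1 TPM in fewer than two
samples are removed unless a transcript encodes an ORF longer than 100
amino acids, and exact spliced-sequence duplicates are dropped.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

from .core import GenomeSequence, TranscriptModel
from .collapse_merge import _group_exonic_overlap


def models_match(
    a: TranscriptModel, b: TranscriptModel, end_window: int = 100
) -> bool:
    """True when two models have identical intron chains on the same
    chrom/strand and both ends within ``end_window`` nt (the TAMA-merge
    "m 0 -a 100 -z 100" matching criterion).  Mono-exonic models must also
    overlap."""
    if (a.chrom, a.strand, a.introns) != (b.chrom, b.strand, b.introns):
        return False
    if not a.introns and not (a.start < b.end and b.start < a.end):
        return False
    return (
        abs(a.five_prime - b.five_prime) <= end_window
        and abs(a.three_prime - b.three_prime) <= end_window
    )


@dataclass
class IntegrationReport:
    """Counts per integration rule, for the summary TSV."""

    iso_kept: int = 0
    rescue_admitted: int = 0
    rescue_dropped: int = 0
    illumina_gene_only: int = 0
    illumina_novel_sj: int = 0
    illumina_dropped: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rule": list(vars(self)), "count": list(vars(self).values())}
        )


def integrate(
    iso_kept: Sequence[TranscriptModel],
    iso_rescue: Sequence[TranscriptModel],
    illumina_models: Sequence[TranscriptModel],
    quant: Optional[pd.DataFrame] = None,
    end_window: int = 100,
    min_length_fraction: float = 0.8,
) -> tuple[list[TranscriptModel], IntegrationReport]:
    """Merge the two transcriptomes under the priority rules above.

    Gene grouping for the rules is recomputed jointly over all input
    models by transitive exonic overlap, so the two sources share loci.
    When ``quant`` is given, every retained transcript must be present in
    it (missing transcripts are an error).
    """
    everything = list(iso_kept) + list(iso_rescue) + list(illumina_models)
    comps = _group_exonic_overlap(everything)
    locus_of: dict[int, int] = {}
    for locus, comp in enumerate(comps):
        for i in comp:
            locus_of[i] = locus

    n_kept = len(iso_kept)
    n_rescue = len(iso_rescue)
    ill_offset = n_kept + n_rescue
    ill_by_locus: dict[int, list[int]] = defaultdict(list)
    for i in range(ill_offset, len(everything)):
        ill_by_locus[locus_of[i]].append(i)

    report = IntegrationReport(iso_kept=n_kept)
    retained_idx: list[int] = list(range(n_kept))

    # rule (b): rescue re-admission
    for i in range(n_kept, ill_offset):
        model = everything[i]
        locus = locus_of[i]
        partners = [everything[j] for j in ill_by_locus.get(locus, [])]
        has_match = any(models_match(model, p, end_window) for p in partners)
        if has_match:
            mean_len = sum(p.spliced_length for p in partners) / len(partners)
            if model.spliced_length >= min_length_fraction * mean_len:
                retained_idx.append(i)
                report.rescue_admitted += 1
                continue
        report.rescue_dropped += 1

    iso_loci = {locus_of[i] for i in retained_idx}
    iso_sj_by_locus: dict[int, set] = defaultdict(set)
    for i in retained_idx:
        iso_sj_by_locus[locus_of[i]].update(everything[i].sj_keys())

    # rule (c): short-read retention
    for i in range(ill_offset, len(everything)):
        model = everything[i]
        locus = locus_of[i]
        if locus not in iso_loci:
            retained_idx.append(i)
            report.illumina_gene_only += 1
        elif any(k not in iso_sj_by_locus[locus] for k in model.sj_keys()):
            retained_idx.append(i)
            report.illumina_novel_sj += 1
        else:
            report.illumina_dropped += 1

    # Relabel gene ids by the joint loci so both sources share gene
    # grouping downstream; transcript ids (the abundance keys) are kept.
    locus_order = sorted(
        {locus_of[i] for i in retained_idx},
        key=lambda l: (everything[comps[l][0]].chrom, min(everything[i].start for i in comps[l])),
    )
    locus_name = {l: f"MERGED_G{k * 10 + 10}" for k, l in enumerate(locus_order)}
    retained = [
        replace(everything[i], gene_id=locus_name[locus_of[i]]) for i in retained_idx
    ]

    if quant is not None:
        missing = [m.transcript_id for m in retained if m.transcript_id not in quant.index]
        if missing:
            raise ValueError(
                f"abundance table missing {len(missing)} retained transcripts, "
                f"e.g. {missing[:3]}"
            )
    return retained, report


def mono_exonic_filter(
    models: Sequence[TranscriptModel],
    quant: pd.DataFrame,
    orf_lengths: Optional[dict[str, int]] = None,
    tpm_threshold: float = 1.0,
    min_samples: int = 2,
    min_orf_aa: int = 100,
    exclude_gene_ids: Optional[set] = None,
) -> list[TranscriptModel]:
    """Remove low-expressed mono-exonic genes.

    A gene whose transcripts are all single-exon is removed when its
    summed TPM exceeds ``tpm_threshold`` in fewer than ``min_samples``
    samples, unless a transcript carries an ORF longer than ``min_orf_aa``
    amino acids.  Multi-exonic genes are untouched.  ``exclude_gene_ids``
    is a hook for user-supplied removals (e.g. rRNA loci).
    """
    orf_lengths = orf_lengths or {}
    exclude_gene_ids = exclude_gene_ids or set()
    by_gene: dict[str, list[TranscriptModel]] = defaultdict(list)
    for m in models:
        by_gene[m.gene_id].append(m)
    out = []
    for gene_id, members in by_gene.items():
        if gene_id in exclude_gene_ids:
            continue
        if any(len(m.exon_blocks) > 1 for m in members):
            out.extend(members)
            continue
        tids = [m.transcript_id for m in members]
        missing = [t for t in tids if t not in quant.index]
        if missing:
            raise ValueError(f"abundance table missing transcripts: {missing[:3]}")
        gene_tpm = quant.loc[tids].sum(axis=0)
        expressed_samples = int((gene_tpm > tpm_threshold).sum())
        has_long_orf = any(orf_lengths.get(t, 0) > min_orf_aa for t in tids)
        if expressed_samples >= min_samples or has_long_orf:
            out.extend(members)
    return out


def remove_duplicate_sequences(
    models: Sequence[TranscriptModel], genome: GenomeSequence
) -> tuple[list[TranscriptModel], list[str]]:
    """Drop models whose spliced sense-strand sequence duplicates an
    earlier one in (gene_id, transcript_id) order.  Returns the kept
    models and the removed transcript ids."""
    seen: set[str] = set()
    kept, removed = [], []
    for m in sorted(models, key=lambda m: (m.gene_id, m.transcript_id)):
        seq = m.spliced_sequence(genome)
        if seq in seen:
            removed.append(m.transcript_id)
        else:
            seen.add(seq)
            kept.append(m)
    return kept, removed
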