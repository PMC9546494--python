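"""End-to-end RTD construction: HC junctions -> end calling -> filtering ->
wobble merge -> (optional) short-read integration and final filters."""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .core import (
    EndObservation,
    GenomeSequence,
    HCFeatureSet,
    ReadAlignment,
    SJTabRecord,
    TranscriptModel,
)
from . import collapse_merge, end_caller, rtd_integrate, sj_filter


@dataclass
class PipelineResult:
    hc_sj_long: set
    hc_sj_short: set
    hc: HCFeatureSet
    collapsed: list[TranscriptModel]
    gene_calls: dict[str, end_caller.GeneEndCalls]
    gene_partition: dict[str, set]
    kept: list[TranscriptModel]
    rescue: list[TranscriptModel]
    removed: list[TranscriptModel]
    merged: list[TranscriptModel]
    merged_rescue: list[TranscriptModel]
    integrated: Optional[list[TranscriptModel]] = None
    integration_report: Optional[rtd_integrate.IntegrationReport] = None
    final: Optional[list[TranscriptModel]] = None
    duplicates_removed: list[str] = field(default_factory=list)


def end_observations_from_models(
    models: Sequence[TranscriptModel], genome: GenomeSequence
) -> dict[str, tuple[list[EndObservation], list[EndObservation], str]]:
    """Per-gene (TSS observations, TES observations, strand), one
    observation per member read of each collapsed model, with the
    internal-priming flag evaluated on the 3' ends."""
    per_gene: dict[str, tuple[list, list, str]] = {}
    for m in models:
        tss_list, tes_list, _ = per_gene.setdefault(m.gene_id, ([], [], m.strand))
        flagged = end_caller.internal_priming_flag(
            m.chrom, m.three_prime, m.strand, genome
        )
        read_ids = m.read_ids or tuple(
            f"{m.transcript_id}#{i}" for i in range(m.read_support)
        )
        for rid in read_ids:
            tss_list.append(
                EndObservation(m.gene_id, rid, "TSS", m.five_prime)
            )
            tes_list.append(
                EndObservation(m.gene_id, rid, "TES", m.three_prime, internal_priming=flagged)
            )
    return per_gene


def build_rtd(
    genome: GenomeSequence,
    alignments: Sequence[ReadAlignment],
    sj_records: Optional[Sequence[SJTabRecord]] = None,
    illumina_models: Optional[Sequence[TranscriptModel]] = None,
    quant: Optional[pd.DataFrame] = None,
    orf_lengths: Optional[dict[str, int]] = None,
    alpha: float = 0.01,
    prefix: str = "RTD",
) -> PipelineResult:
    """Run the full construction pipeline on digested alignments.

    Long-read stages always run; integration, the mono-exonic expression
    filter and duplicate removal run when short-read models / abundances
    are supplied.
    """
    primary = [a for a in alignments if not a.is_supplementary]
    evidence = sj_filter.collect_sj_evidence(primary, genome)
    hc_long = sj_filter.hc_sj_longread(evidence.values())
    hc_short = (
        sj_filter.hc_sj_shortread(sj_records, genome) if sj_records else set()
    )

    collapsed = collapse_merge.collapse_reads(primary, prefix=prefix)
    per_gene = end_observations_from_models(collapsed, genome)
    gene_calls = {}
    hc = HCFeatureSet(hc_sj=hc_long)
    for gene_id, (tss_obs, tes_obs, strand) in per_gene.items():
        calls = end_caller.call_gene_ends(tss_obs, tes_obs, strand, alpha=alpha)
        calls.gene_id = gene_id
        gene_calls[gene_id] = calls
        if calls.called:
            hc.tss[gene_id] = calls.tss
            hc.tes[gene_id] = calls.tes
    partition = end_caller.classify_genes(gene_calls.values())

    kept, rescue, removed = collapse_merge.filter_transcripts(collapsed, hc)
    merged = collapse_merge.wobble_merge(kept)
    merged_rescue = collapse_merge.wobble_merge(rescue)

    result = PipelineResult(
        hc_sj_long=hc_long,
        hc_sj_short=hc_short,
        hc=hc,
        collapsed=collapsed,
        gene_calls=gene_calls,
        gene_partition=partition,
        kept=kept,
        rescue=rescue,
        removed=removed,
        merged=merged,
        merged_rescue=merged_rescue,
    )

    if illumina_models is not None:
        integrated, report = rtd_integrate.integrate(
            merged, merged_rescue, list(illumina_models), quant=quant
        )
        result.integrated = integrated
        result.integration_report = report
        final = integrated
        if quant is not None:
            final = rtd_integrate.mono_exonic_filter(
                final, quant, orf_lengths=orf_lengths
            )
        final, dropped = rtd_integrate.remove_duplicate_sequences(final, genome)
        result.final = final
        result.duplicates_removed = dropped
    return result
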