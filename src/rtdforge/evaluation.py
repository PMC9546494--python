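"""Benchmarking a candidate RTD.

Two validations are provided: chimeric-transcript counting against
independently sequenced full-length cDNA (flcDNA) genome mappings, and
correlation of alternative-splicing ratios between RT-PCR product
proportions and RNA-seq transcript abundances (TPM).
"""

from __future__ import annotations

from bisect import bisect_left
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .core import TranscriptModel


@dataclass(frozen=True)
class RTPCRRecord:
    """One RT-PCR product proportion measurement.

    ``proportion`` is the product's fraction of total fluorescence for its
    primer pair in one sample; ``transcript_ids`` are the RTD transcripts
    the product maps to.
    """

    primer_pair: str
    product: str
    sample: str
    proportion: float
    transcript_ids: tuple[str, ...]


def chimera_count(
    candidate_models: Sequence[TranscriptModel],
    flcdna_models: Sequence[TranscriptModel],
) -> tuple[int, float]:
    """Count candidate transcripts overlapping more than one flcDNA.

    Overlap is >= 1 bp of genomic-span intersection on the same strand
    (whole-feature, not exon-level).  Returns ``(n_chimeric, fraction)``.
    """
    by_group: dict[tuple, list[tuple[int, int]]] = defaultdict(list)
    for f in flcdna_models:
        by_group[(f.chrom, f.strand)].append((f.start, f.end))
    for spans in by_group.values():
        spans.sort()
    n_chimeric = 0
    for m in candidate_models:
        spans = by_group.get((m.chrom, m.strand), [])
        hits = 0
        # spans sorted by start; scan the window that can overlap [start, end)
        starts = [s for s, _ in spans]
        i = bisect_left(starts, m.end)
        for s, e in spans[:i]:
            if e > m.start:
                hits += 1
                if hits >= 2:
                    break
        if hits >= 2:
            n_chimeric += 1
    fraction = n_chimeric / len(candidate_models) if candidate_models else 0.0
    return n_chimeric, fraction


def splicing_ratio_correlation(
    rtpcr: Sequence[RTPCRRecord], quant: pd.DataFrame
) -> tuple[float, float, pd.DataFrame]:
    """Correlate RT-PCR splicing ratios with RNA-seq TPM ratios.

    For each (primer pair, sample), the RNA-seq ratio of a product is the
    summed TPM of its transcripts divided by the summed TPM over all the
    primer pair's products in that sample; pairs with zero total TPM are
    dropped.  Returns Pearson r, Spearman rho and the paired table.
    """
    for rec in rtpcr:
        missing = [t for t in rec.transcript_ids if t not in quant.index]
        if missing:
            raise ValueError(
                f"product {rec.product}: transcripts absent from quant: {missing}"
            )
    by_pair_sample: dict[tuple[str, str], list[RTPCRRecord]] = defaultdict(list)
    for rec in rtpcr:
        if rec.sample not in quant.columns:
            raise ValueError(f"sample {rec.sample!r} absent from quant")
        by_pair_sample[(rec.primer_pair, rec.sample)].append(rec)
    rows = []
    for (pair, sample), records in sorted(by_pair_sample.items()):
        tpms = {
            rec.product: float(quant.loc[list(rec.transcript_ids), sample].sum())
            for rec in records
        }
        total = sum(tpms.values())
        if total <= 0:
            continue  # no RNA-seq signal for this primer pair in this sample
        for rec in records:
            rows.append(
                {
                    "primer_pair": pair,
                    "product": rec.product,
                    "sample": sample,
                    "measured_ratio": rec.proportion,
                    "rnaseq_ratio": tpms[rec.product] / total,
                }
            )
    table = pd.DataFrame(rows)
    if len(table) < 2:
        return float("nan"), float("nan"), table
    pearson = float(pearsonr(table["measured_ratio"], table["rnaseq_ratio"])[0])
    spearman = float(spearmanr(table["measured_ratio"], table["rnaseq_ratio"])[0])
    return pearson, spearman, table
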