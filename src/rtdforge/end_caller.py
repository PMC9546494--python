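"""Calling high-confidence transcript start (TSS) and end (TES) sites.

Long-read 5'/3' end positions within a gene are modelled as draws over the
gene's observed end sites: degradation products scatter uniformly, real
sites recruit more reads than expected at random.  For each candidate site
the binomial point mass

    Pr(Reads = h) = C(n, h) (1/t)^h (1 - 1/t)^(n - h)

is evaluated, where n is the total number of reads in the gene, h the
reads at the tested site and t the number of distinct observed sites; a
site is called when this probability is below ``alpha`` (default 0.01).
Observations within an attachment window of a called site (+-10 nt for
TSS, +-30 nt for TES) are assigned to it; the rest are discarded.

Genes where no site reaches significance (typically < 10 reads) fall back
to a fixed sliding window: any cluster of end positions within +-20 nt
(TSS) or +-60 nt (TES) supported by 2 or more reads is called at its
support-weighted modal position.

Putative internal-priming 3' ends — more than 16 A (transcript sense) in
the 20 genomic nucleotides following the end — are removed before calling.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from scipy.stats import binom

from .core import EndObservation, EndSite, GenomeSequence

ATTACH_WINDOW = {"TSS": 10, "TES": 30}
FIXED_WINDOW = {"TSS": 20, "TES": 60}

IP_WINDOW = 20
IP_MAX_A = 16


def internal_priming_flag(
    chrom: str, tes_position: int, strand: str, genome: GenomeSequence
) -> bool:
    """True when the 20 nt downstream (transcription direction) of a 3' end
    contain more than 16 A on the transcript sense strand.

    ``tes_position`` is the half-open 3' boundary of the read/transcript:
    the window is ``[pos, pos + 20)`` counting A on the plus strand, and
    ``[pos - 20, pos)`` counting T on the minus strand.  The window is
    truncated at contig edges and the count taken over available bases.
    """
    if strand == "+":
        seq = genome.fetch_padded(chrom, tes_position, tes_position + IP_WINDOW, pad="")
        return seq.count("A") > IP_MAX_A
    seq = genome.fetch_padded(chrom, tes_position - IP_WINDOW, tes_position, pad="")
    return seq.count("T") > IP_MAX_A


def binomial_point_mass(h: int, n: int, t: int) -> float:
    """Probability of exactly ``h`` of ``n`` reads landing on one of ``t``
    equally likely sites; computed in log space by scipy for stability."""
    if t < 1:
        raise ValueError("t must be >= 1")
    if not 0 <= h <= n:
        raise ValueError("h must satisfy 0 <= h <= n")
    if t == 1:
        return 1.0 if h == n else 0.0
    return float(binom.pmf(h, n, 1.0 / t))


def _five_most(positions: Iterable[int], strand: str) -> int:
    """Transcription-direction 5'-most coordinate (used for tie-breaks)."""
    return min(positions) if strand == "+" else max(positions)


def call_enriched_ends(
    observations: Sequence[EndObservation],
    kind: str,
    strand: str = "+",
    alpha: float = 0.01,
    attach_window: Optional[int] = None,
    bonferroni: bool = False,
    window_support: bool = True,
) -> tuple[list[EndSite], list[EndObservation], list[EndObservation]]:
    """Binomial-enrichment end calling for one gene.

    Returns ``(sites, retained, removed)``.  A candidate position is
    significant when the binomial point mass of its support is below
    ``alpha``.  Because real end positions are stochastic around a
    dominant site, ``window_support=True`` (default) takes h as the read
    support within the attachment window of the candidate, and keeps only
    local maxima (no two called sites within one window);
    ``window_support=False`` uses the exact per-position read count.
    Observations within the attachment window of a called site are
    assigned to the nearest one, the rest are removed.  ``bonferroni``
    optionally divides ``alpha`` by the number of distinct sites tested.
    """
    if attach_window is None:
        attach_window = ATTACH_WINDOW[kind]
    if not observations:
        return [], [], []
    counts = Counter(obs.position for obs in observations)
    n = len(observations)
    t = len(counts)
    threshold = alpha / t if bonferroni else alpha
    positions = sorted(counts)
    called: dict[int, tuple[int, float]] = {}
    if not window_support:
        # literal per-position test: point mass of the exact read count
        for pos in positions:
            p = binomial_point_mass(counts[pos], n, t)
            if p < threshold:
                called[pos] = (counts[pos], p)
    else:
        # Read ends scatter around dominant sites, so candidate support is
        # aggregated within the attachment window.  A candidate is called
        # when either (i) its exact-position count is a significant point
        # mass (the per-site test above), or (ii) its windowed support is
        # enriched against the uniform-scatter null, where a random end
        # falls inside the window with probability (2w+1)/span.  Sites are
        # claimed greedily (strongest first) and claimed observations do
        # not support further candidates, so shoulders of an already
        # called peak cannot re-trigger.
        span = positions[-1] - positions[0] + 1
        p_window = min(1.0, (2 * attach_window + 1) / span)
        # the scatter null is only meaningful when ends actually scatter;
        # with few distinct positions the per-site test decides alone
        use_window = t >= 10
        unclaimed = dict(counts)

        def candidate(pos):
            h_exact = unclaimed.get(pos, 0)
            h_window = sum(
                c for q, c in unclaimed.items() if abs(q - pos) <= attach_window
            )
            if h_exact and binomial_point_mass(h_exact, n, t) < threshold:
                return h_window, binomial_point_mass(h_exact, n, t)
            if use_window and h_window and h_window >= n * p_window:
                p = float(binom.pmf(h_window, n, p_window))
                if p < threshold:
                    return h_window, p
            return None

        while True:
            best = None
            for pos in positions:
                if pos in called:
                    continue
                hit = candidate(pos)
                if hit is None:
                    continue
                key = (hit[0], -pos if strand == "+" else pos)
                if best is None or key > best[0]:
                    best = (key, pos, hit)
            if best is None:
                break
            _, pos, hit = best
            called[pos] = hit
            for q in [q for q in unclaimed if abs(q - pos) <= attach_window]:
                del unclaimed[q]
    if not called:
        return [], [], list(observations)
    gene_id = observations[0].gene_id
    attached: dict[int, list[EndObservation]] = {pos: [] for pos in called}
    removed = []
    for obs in observations:
        best = None
        best_d = attach_window + 1
        for pos in called:
            d = abs(obs.position - pos)
            if d < best_d or (d == best_d and best is not None and
                              pos == _five_most((pos, best), strand)):
                best, best_d = pos, d
        if best is not None and best_d <= attach_window:
            attached[best].append(obs)
        else:
            removed.append(obs)
    sites = [
        EndSite(
            gene_id=gene_id,
            kind=kind,
            position=pos,
            supporting_reads=len(attached[pos]),
            method="binomial",
            p_value=called[pos][1],
        )
        for pos in sorted(called, key=lambda p: (p if strand == "+" else -p))
    ]
    retained = [obs for pos in called for obs in attached[pos]]
    return sites, retained, removed


def fixed_window_ends(
    observations: Sequence[EndObservation],
    kind: str,
    strand: str = "+",
    min_reads: int = 2,
    window: Optional[int] = None,
) -> tuple[list[EndSite], list[EndObservation], list[EndObservation]]:
    """Sliding-window fallback for genes without binomially enriched sites.

    Greedy clustering: repeatedly take the unclustered position with the
    highest read support (ties resolved toward the transcription-direction
    5'-most coordinate), gather all observations within the window, and
    emit a site at the support-weighted modal position when the cluster
    holds ``min_reads`` or more reads.
    """
    if window is None:
        window = FIXED_WINDOW[kind]
    if not observations:
        return [], [], []
    gene_id = observations[0].gene_id
    counts = Counter(obs.position for obs in observations)
    remaining = dict(counts)
    sites = []
    accepted_spans: list[tuple[int, int]] = []
    while remaining:
        top = max(
            remaining,
            key=lambda p: (remaining[p], p if strand == "-" else -p),
        )
        cluster = {p: c for p, c in remaining.items() if abs(p - top) <= window}
        support = sum(cluster.values())
        if support >= min_reads:
            best = max(
                cluster,
                key=lambda p: (cluster[p], p if strand == "-" else -p),
            )
            sites.append(
                EndSite(
                    gene_id=gene_id,
                    kind=kind,
                    position=best,
                    supporting_reads=support,
                    method="fixed_window",
                )
            )
            accepted_spans.append((top - window, top + window))
        for p in cluster:
            del remaining[p]
    retained, removed = [], []
    for obs in observations:
        if any(lo <= obs.position <= hi for lo, hi in accepted_spans):
            retained.append(obs)
        else:
            removed.append(obs)
    sites.sort(key=lambda s: (s.position if strand == "+" else -s.position))
    return sites, retained, removed


@dataclass
class GeneEndCalls:
    """Result of end calling for one gene."""

    gene_id: str
    tss: list[EndSite] = field(default_factory=list)
    tes: list[EndSite] = field(default_factory=list)
    retained_tss: list[EndObservation] = field(default_factory=list)
    retained_tes: list[EndObservation] = field(default_factory=list)

    @property
    def called(self) -> bool:
        return bool(self.tss) and bool(self.tes)

    @property
    def any_binomial(self) -> bool:
        return any(s.method == "binomial" for s in self.tss + self.tes)


def call_gene_ends(
    tss_obs: Sequence[EndObservation],
    tes_obs: Sequence[EndObservation],
    strand: str,
    alpha: float = 0.01,
    min_reads: int = 2,
    bonferroni: bool = False,
    window_support: bool = True,
) -> GeneEndCalls:
    """Call TSS and TES for one gene: binomial enrichment first, fixed
    window when no site of that kind reaches significance.  Internal-
    priming-flagged TES observations are dropped before calling."""
    tes_obs = [o for o in tes_obs if not o.internal_priming]
    gene_id = (list(tss_obs) + list(tes_obs) or [EndObservation("", "", "TSS", 0)])[0].gene_id
    result = GeneEndCalls(gene_id=gene_id)
    for kind, obs in (("TSS", list(tss_obs)), ("TES", list(tes_obs))):
        sites, retained, _ = call_enriched_ends(
            obs, kind, strand=strand, alpha=alpha, bonferroni=bonferroni,
            window_support=window_support,
        )
        if not sites:
            sites, retained, _ = fixed_window_ends(
                obs, kind, strand=strand, min_reads=min_reads
            )
        if kind == "TSS":
            result.tss, result.retained_tss = sites, retained
        else:
            result.tes, result.retained_tes = sites, retained
    return result


def classify_genes(calls: Iterable[GeneEndCalls]) -> dict[str, set[str]]:
    """Partition genes into ``binomial_called`` (both ends available, at
    least one site from the binomial test), ``fixed_window_called`` (both
    ends, fixed-window only) and ``rescue`` (fewer than two concordant
    ends; their HC-junction transcripts are carried forward separately)."""
    partition = {"binomial_called": set(), "fixed_window_called": set(), "rescue": set()}
    for c in calls:
        if not c.called:
            partition["rescue"].add(c.gene_id)
        elif c.any_binomial:
            partition["binomial_called"].add(c.gene_id)
        else:
            partition["fixed_window_called"].add(c.gene_id)
    return partition
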