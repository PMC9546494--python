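"""Core domain types shared across the toolkit.

All genomic coordinates are 0-based half-open.  Exon blocks are always
stored in genomic (leftmost-first) order, regardless of strand; 5'/3'
ends are derived strand-aware by the accessors below.  The position of a
transcript end is the half-open boundary on that side of the outermost
block: for a plus-strand model the 5' end is ``blocks[0].start`` and the
3' end is ``blocks[-1].end``; on the minus strand the roles swap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Optional, Sequence

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

Interval = tuple[int, int]


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence(Mapping[str, str]):
    """Immutable name -> uppercase DNA sequence mapping.

    Lookup is case-insensitive on the contig name; sequences are stored
    uppercase.  Substring extraction beyond contig bounds is an error
    (:meth:`fetch`); :meth:`fetch_padded` instead pads out-of-bounds
    positions with a sentinel character, which downstream Hamming-distance
    comparisons treat as never-matching.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: dict[str, str] = {}
        self._canonical: dict[str, str] = {}
        for name, seq in sequences.items():
            key = name.lower()
            if key in self._canonical:
                raise ValueError(f"duplicate contig name: {name!r}")
            self._canonical[key] = name
            self._seqs[name] = seq.upper()
        if not self._seqs:
            raise ValueError("genome contains no sequences")

    def __getitem__(self, name: str) -> str:
        try:
            return self._seqs[self._canonical[name.lower()]]
        except KeyError:
            raise KeyError(f"contig {name!r} not in genome") from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise ValueError(
                f"interval [{start}, {end}) out of bounds for {chrom} "
                f"(length {len(seq)})"
            )
        return seq[start:end]

    def fetch_padded(self, chrom: str, start: int, end: int, pad: str = "?") -> str:
        """Like :meth:`fetch` but out-of-bounds positions become ``pad``."""
        seq = self[chrom]
        lo, hi = max(start, 0), min(end, len(seq))
        if lo >= hi:
            return pad * (end - start)
        return pad * (lo - start) + seq[lo:hi] + pad * (end - hi)


def _check_blocks(blocks: Sequence[Interval]) -> tuple[Interval, ...]:
    blocks = tuple((int(s), int(e)) for s, e in blocks)
    if not blocks:
        raise ValueError("at least one exon block is required")
    for s, e in blocks:
        if s >= e:
            raise ValueError(f"empty or inverted block [{s}, {e})")
    for (s0, e0), (s1, e1) in zip(blocks, blocks[1:]):
        if e0 > s1:
            raise ValueError("exon blocks must be sorted and non-overlapping")
    return blocks


@dataclass(frozen=True)
class ReadAlignment:
    """One mapped full-length read, digested to exon blocks.

    ``mismatch_positions`` are 0-based genomic positions of substitutions
    (indels are not recorded); every position lies inside an exon block.
    """

    read_id: str
    chrom: str
    strand: str
    exon_blocks: tuple[Interval, ...]
    mismatch_positions: tuple[int, ...] = ()
    is_supplementary: bool = False

    def __post_init__(self):
        object.__setattr__(self, "exon_blocks", _check_blocks(self.exon_blocks))
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        mism = tuple(sorted(int(p) for p in self.mismatch_positions))
        for p in mism:
            if not any(s <= p < e for s, e in self.exon_blocks):
                raise ValueError(f"mismatch position {p} outside exon blocks")
        object.__setattr__(self, "mismatch_positions", mism)

    @property
    def introns(self) -> tuple[Interval, ...]:
        b = self.exon_blocks
        return tuple((b[i][1], b[i + 1][0]) for i in range(len(b) - 1))

    @property
    def start(self) -> int:
        return self.exon_blocks[0][0]

    @property
    def end(self) -> int:
        return self.exon_blocks[-1][1]

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class TranscriptModel:
    """An exon-block transcript model.

    ``read_support`` is the number of long reads collapsed into the model
    (1 for short-read assembled models).  ``read_ids`` optionally records
    the member reads for models produced by collapsing.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exon_blocks: tuple[Interval, ...]
    source: str = "isoseq"
    read_support: int = 1
    read_ids: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "exon_blocks", _check_blocks(self.exon_blocks))
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.read_support < 0:
            raise ValueError("read_support must be non-negative")

    @property
    def introns(self) -> tuple[Interval, ...]:
        b = self.exon_blocks
        return tuple((b[i][1], b[i + 1][0]) for i in range(len(b) - 1))

    @property
    def start(self) -> int:
        return self.exon_blocks[0][0]

    @property
    def end(self) -> int:
        return self.exon_blocks[-1][1]

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exon_blocks)

    def sj_keys(self) -> tuple[tuple, ...]:
        """Junction identity keys (chrom, strand, intron start, intron end)."""
        return tuple((self.chrom, self.strand, s, e) for s, e in self.introns)

    def spliced_sequence(self, genome: GenomeSequence) -> str:
        seq = "".join(genome.fetch(self.chrom, s, e) for s, e in self.exon_blocks)
        return seq if self.strand == "+" else reverse_complement(seq)

    def with_ids(self, gene_id: str, transcript_id: str) -> "TranscriptModel":
        return replace(self, gene_id=gene_id, transcript_id=transcript_id)


@dataclass(frozen=True)
class SJTabRecord:
    """One STAR-style short-read splice junction record.

    Stored 0-based half-open; ``strand`` is '+', '-' or None (undefined).
    """

    chrom: str
    start: int
    end: int
    strand: Optional[str]
    motif_code: int = 0
    unique_reads: int = 0
    max_overhang: int = 0

    def __post_init__(self):
        if self.end - self.start < 1:
            raise ValueError("intron interval must have length >= 1")
        if self.unique_reads < 0 or self.max_overhang < 0:
            raise ValueError("counts must be non-negative")
        if self.strand not in ("+", "-", None):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class SpliceJunction:
    """A strand-aware intron interval with sense-strand splice dinucleotides."""

    chrom: str
    strand: str
    start: int
    end: int
    donor: str
    acceptor: str

    @property
    def key(self) -> tuple:
        return (self.chrom, self.strand, self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SJEvidence:
    """Aggregated read evidence for one unique splice junction."""

    junction: SpliceJunction
    supporting_read_count: int = 0
    clean_read_count: int = 0
    template_switch: bool = False
    hd_donor: int = 8
    hd_acceptor: int = 8


@dataclass(frozen=True)
class EndObservation:
    """One read's 5' or 3' end position within a gene."""

    gene_id: str
    read_id: str
    kind: str  # "TSS" or "TES"
    position: int
    internal_priming: bool = False


@dataclass(frozen=True)
class EndSite:
    """A called transcript start or end site."""

    gene_id: str
    kind: str
    position: int
    supporting_reads: int
    method: str  # "binomial" or "fixed_window"
    p_value: Optional[float] = None


@dataclass
class HCFeatureSet:
    """High-confidence junctions plus per-gene called end sites.

    This is the filtering oracle used to retain transcript models: keys in
    ``hc_sj`` are ``(chrom, strand, intron_start, intron_end)`` tuples and
    ``tss``/``tes`` map gene ids to called site positions.
    """

    hc_sj: set = field(default_factory=set)
    tss: dict[str, list[EndSite]] = field(default_factory=dict)
    tes: dict[str, list[EndSite]] = field(default_factory=dict)

    def gene_has_ends(self, gene_id: str) -> bool:
        return bool(self.tss.get(gene_id)) and bool(self.tes.get(gene_id))
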