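import numpy as np
import pytest

from rtdforge.core import GenomeSequence, ReadAlignment, TranscriptModel


def make_genome(rng_or_seed=0, length=2000, name="chr1", gc=0.45, edits=None):
    """Random genome with optional {position: base-string} edits."""
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = list("".join(np.random.default_rng(rng.integers(2**31)).choice(
        list("ACGT"), size=length, p=p)))
    for pos, bases in (edits or {}).items():
        seq[pos : pos + len(bases)] = list(bases)
    return GenomeSequence({name: "".join(seq)})


@pytest.fixture
def flat_genome():
    """A deterministic 2 kb single-contig genome."""
    return make_genome(0, 2000)


def model(blocks, strand="+", chrom="chr1", tid="t1", gid="g1", support=1,
          source="isoseq"):
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gid,
        chrom=chrom,
        strand=strand,
        exon_blocks=tuple(blocks),
        source=source,
        read_support=support,
    )


def read(blocks, strand="+", chrom="chr1", rid="r1", mismatches=()):
    return ReadAlignment(
        read_id=rid,
        chrom=chrom,
        strand=strand,
        exon_blocks=tuple(blocks),
        mismatch_positions=tuple(mismatches),
    )
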