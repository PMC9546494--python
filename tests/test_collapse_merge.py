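"""Read collapsing, HC filtering and end-wobble merging."""

import numpy as np
import pytest

from rtdforge import collapse_merge
from rtdforge.core import EndSite, HCFeatureSet

from conftest import model, read


def site(gene, kind, position):
    return EndSite(gene, kind, position, supporting_reads=5, method="fixed_window")


class TestCollapse:
    def test_identical_reads_become_one_model(self):
        reads = [
            read([(0, 50), (100, 200)], rid=f"r{i}") for i in range(3)
        ]
        (m,) = collapse_merge.collapse_reads(reads)
        assert m.read_support == 3
        assert set(m.read_ids) == {"r0", "r1", "r2"}

    def test_one_bp_resolution(self):
        reads = [
            read([(0, 50), (100, 200)], rid="a"),
            read([(1, 50), (100, 200)], rid="b"),  # start differs by 1 nt
        ]
        models = collapse_merge.collapse_reads(reads)
        assert len(models) == 2
        assert len({m.gene_id for m in models}) == 1

    def test_opposite_strands_are_separate_genes(self):
        reads = [
            read([(0, 200)], rid="a", strand="+"),
            read([(50, 250)], rid="b", strand="-"),
        ]
        models = collapse_merge.collapse_reads(reads)
        assert len({m.gene_id for m in models}) == 2

    def test_gene_grouping_is_transitive(self):
        # a-b overlap, b-c overlap, a-c do not: still one gene
        reads = [
            read([(0, 100)], rid="a"),
            read([(80, 220)], rid="b"),
            read([(200, 300)], rid="c"),
        ]
        models = collapse_merge.collapse_reads(reads)
        assert len({m.gene_id for m in models}) == 1

    def test_intron_overlap_alone_does_not_group(self):
        # second read lies entirely inside the first read's intron
        reads = [
            read([(0, 50), (500, 600)], rid="a"),
            read([(100, 400)], rid="b"),
        ]
        models = collapse_merge.collapse_reads(reads)
        assert len({m.gene_id for m in models}) == 2

    def test_supplementary_alignments_skipped(self):
        from rtdforge.core import ReadAlignment

        reads = [
            read([(0, 100)], rid="a"),
            ReadAlignment("b", "chr1", "+", ((0, 100),), is_supplementary=True),
        ]
        (m,) = collapse_merge.collapse_reads(reads)
        assert m.read_support == 1


class TestFilter:
    def _hc(self, tss=100, tes=900, sjs=()):
        return HCFeatureSet(
            hc_sj=set(sjs),
            tss={"g": [site("g", "TSS", tss)]},
            tes={"g": [site("g", "TES", tes)]},
        )

    def _model(self, start, end, gid="g"):
        blocks = [(start, 400), (500, end)]
        m = model(blocks, gid=gid, tid="t")
        return m

    def test_within_windows_and_hc_sjs_kept(self):
        m = self._model(108, 925)  # offsets 8 and 25
        hc = self._hc(sjs=m.sj_keys())
        kept, rescue, removed = collapse_merge.filter_transcripts([m], hc)
        assert kept == [m]

    @pytest.mark.parametrize("start,end,ok", [
        (110, 900, True),   # TSS offset exactly 10
        (111, 900, False),  # TSS offset 11
        (100, 930, True),   # TES offset exactly 30
        (100, 931, False),  # TES offset 31
    ])
    def test_window_boundaries(self, start, end, ok):
        m = self._model(start, end)
        hc = self._hc(sjs=m.sj_keys())
        kept, _, removed = collapse_merge.filter_transcripts([m], hc)
        assert (m in kept) is ok

    def test_non_hc_junction_removed(self):
        m = self._model(100, 900)
        hc = self._hc(sjs=())  # junction not in the HC set
        kept, rescue, removed = collapse_merge.filter_transcripts([m], hc)
        assert removed == [m]

    def test_gene_without_called_ends_goes_to_rescue(self):
        m = self._model(100, 900, gid="other")
        hc = self._hc(sjs=m.sj_keys())
        kept, rescue, removed = collapse_merge.filter_transcripts([m], hc)
        assert rescue == [m]

    def test_rescue_requires_hc_junctions(self):
        m = self._model(100, 900, gid="other")
        hc = self._hc(sjs=())
        _, rescue, removed = collapse_merge.filter_transcripts([m], hc)
        assert removed == [m]


class TestWobbleMerge:
    def test_most_abundant_ends_win(self):
        a = model([(100, 400), (500, 900)], tid="a", support=3)
        b = model([(150, 400), (500, 980)], tid="b", support=1)
        (merged,) = collapse_merge.wobble_merge([a, b])
        assert merged.exon_blocks == ((100, 400), (500, 900))
        assert merged.read_support == 4

    def test_far_ends_not_merged(self):
        a = model([(100, 400), (500, 900)], tid="a")
        b = model([(251, 400), (500, 900)], tid="b")  # 5' ends differ 151
        assert len(collapse_merge.wobble_merge([a, b])) == 2

    @pytest.mark.parametrize("delta,n_out", [(100, 1), (101, 2)])
    def test_tolerance_boundary(self, delta, n_out):
        a = model([(100, 400), (500, 900)], tid="a")
        b = model([(100 + delta, 400), (500, 900)], tid="b")
        assert len(collapse_merge.wobble_merge([a, b])) == n_out

    def test_different_sj_chains_never_merge(self):
        a = model([(100, 400), (500, 900)], tid="a")
        b = model([(100, 401), (500, 900)], tid="b")
        assert len(collapse_merge.wobble_merge([a, b])) == 2

    def test_single_model_unchanged(self):
        a = model([(100, 400), (500, 900)], tid="a")
        assert collapse_merge.wobble_merge([a]) == [a]

    def test_mono_exonic_requires_overlap(self):
        a = model([(100, 160)], tid="a")
        b = model([(200, 260)], tid="b")  # ends within 100 but disjoint
        assert len(collapse_merge.wobble_merge([a, b])) == 2
        c = model([(150, 260)], tid="c")
        assert len(collapse_merge.wobble_merge([a, c])) == 1

    def test_minus_strand_tie_breaks_toward_five_prime(self):
        a = model([(100, 400), (500, 900)], tid="a", strand="-", support=2)
        b = model([(120, 400), (500, 880)], tid="b", strand="-", support=2)
        (merged,) = collapse_merge.wobble_merge([a, b])
        # on the minus strand "5'-most" is the larger coordinate, for
        # both the 5' (right) and the 3' (left) boundary
        assert merged.end == 900
        assert merged.start == 120

    def _random_models(self, rng, n):
        out = []
        for i in range(n):
            chrom = f"chr{rng.integers(1, 3)}"
            strand = "+" if rng.integers(2) else "-"
            base = int(rng.integers(0, 5_000))
            n_introns = int(rng.integers(0, 3))
            bounds = [base]
            for _ in range(2 * n_introns + 1):
                bounds.append(bounds[-1] + int(rng.integers(30, 200)))
            blocks = [
                (bounds[j] + int(rng.integers(-60, 60)) * (j == 0), bounds[j + 1])
                for j in range(0, len(bounds) - 1, 2)
            ]
            blocks[0] = (min(blocks[0][0], blocks[0][1] - 10), blocks[0][1])
            out.append(
                model(blocks, strand=strand, chrom=chrom, tid=f"t{i}",
                      support=int(rng.integers(1, 9)))
            )
        return out

    def test_idempotence_support_conservation_no_residual_pairs(self):
        from rtdforge.rtd_integrate import models_match

        rng = np.random.default_rng(17)
        models = self._random_models(rng, 600)
        merged = collapse_merge.wobble_merge(models)
        assert sum(m.read_support for m in merged) == sum(
            m.read_support for m in models
        )
        assert collapse_merge.wobble_merge(merged) == merged
        for i, a in enumerate(merged):
            for b in merged[i + 1 :]:
                assert not models_match(a, b)


def test_gene_id_assignment_is_stable():
    models = [
        model([(500, 700)], tid="x", support=1),
        model([(550, 800)], tid="y", support=5),
        model([(2000, 2200)], tid="z", support=2),
    ]
    named = collapse_merge.assign_gene_ids(models, prefix="RTD")
    assert named[0].gene_id == named[1].gene_id == "RTDchr1G10"
    assert named[2].gene_id == "RTDchr1G20"
    # transcript suffixes ordered by descending support
    assert named[1].transcript_id == "RTDchr1G10.1"
    assert named[0].transcript_id == "RTDchr1G10.2"
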