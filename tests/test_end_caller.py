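"""Binomial and fixed-window TSS/TES calling."""

from fractions import Fraction

import numpy as np
import pytest

from rtdforge import end_caller
from rtdforge.core import EndObservation, GenomeSequence


def obs(positions, gene="g1", kind="TSS"):
    return [
        EndObservation(gene, f"r{i}", kind, p) for i, p in enumerate(positions)
    ]


def exact_mass(h, n, t):
    """Independent rational-arithmetic oracle for the binomial point mass."""
    from math import comb

    return comb(n, h) * Fraction(1, t) ** h * Fraction(t - 1, t) ** (n - h)


class TestBinomialPointMass:
    def test_half_split(self):
        # C(10,5) / 2^10 exactly
        assert end_caller.binomial_point_mass(5, 10, 2) == pytest.approx(
            0.24609375, abs=1e-15
        )

    def test_single_site_takes_all_reads(self):
        assert end_caller.binomial_point_mass(7, 7, 1) == 1.0
        assert end_caller.binomial_point_mass(0, 7, 1) == 0.0

    def test_empty_site(self):
        # (4/5)^5
        assert end_caller.binomial_point_mass(0, 5, 5) == pytest.approx(
            0.32768, abs=1e-12
        )

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            end_caller.binomial_point_mass(5, 4, 2)
        with pytest.raises(ValueError):
            end_caller.binomial_point_mass(1, 4, 0)
        with pytest.raises(ValueError):
            end_caller.binomial_point_mass(-1, 4, 2)

    def test_matches_rational_oracle(self):
        for n in (1, 5, 17, 30):
            for t in (2, 3, 7, 10):
                for h in range(n + 1):
                    assert end_caller.binomial_point_mass(h, n, t) == pytest.approx(
                        float(exact_mass(h, n, t)), abs=1e-12
                    )

    def test_sums_to_one(self):
        for n, t in [(10, 3), (100, 7), (1000, 100), (1000, 2)]:
            total = sum(
                end_caller.binomial_point_mass(h, n, t) for h in range(n + 1)
            )
            assert total == pytest.approx(1.0, abs=1e-12)


class TestInternalPriming:
    def _genome(self, n_a, strand="+"):
        window = "A" * n_a + "G" * (20 - n_a)
        if strand == "+":
            return GenomeSequence({"chr1": "C" * 100 + window + "C" * 100})
        rc = window[::-1].translate(str.maketrans("AG", "TC"))
        return GenomeSequence({"chr1": "C" * 80 + rc + "C" * 120})

    def test_seventeen_a_flagged(self):
        assert end_caller.internal_priming_flag("chr1", 100, "+", self._genome(17))

    def test_sixteen_a_not_flagged(self):
        assert not end_caller.internal_priming_flag("chr1", 100, "+", self._genome(16))

    def test_no_a_not_flagged(self):
        assert not end_caller.internal_priming_flag("chr1", 100, "+", self._genome(0))

    def test_minus_strand_counts_t_upstream(self):
        assert end_caller.internal_priming_flag("chr1", 100, "-", self._genome(17, "-"))
        assert not end_caller.internal_priming_flag("chr1", 100, "-", self._genome(16, "-"))

    def test_window_truncated_at_contig_end(self):
        genome = GenomeSequence({"chr1": "C" * 95 + "AAAAA"})
        assert not end_caller.internal_priming_flag("chr1", 95, "+", genome)


class TestEnrichedEnds:
    def test_dominant_site_called_and_outliers_removed(self):
        positions = [500] * 15 + [100, 220, 340, 460, 900]
        sites, retained, removed = end_caller.call_enriched_ends(
            obs(positions), "TSS"
        )
        assert [s.position for s in sites] == [500]
        assert sites[0].p_value < 0.01
        assert len(retained) == 15
        assert {o.position for o in removed} == {100, 220, 340, 460, 900}

    def test_two_balanced_reads_call_nothing(self):
        # n=2, t=2, h=1: mass 0.5 each
        sites, retained, removed = end_caller.call_enriched_ends(
            obs([100, 400]), "TSS"
        )
        assert sites == [] and len(removed) == 2

    def test_observation_within_window_attaches(self):
        positions = [500] * 15 + [508] + [100, 220, 340, 460]
        sites, retained, _ = end_caller.call_enriched_ends(obs(positions), "TSS")
        assert [s.position for s in sites] == [500]
        assert sum(1 for o in retained if o.position == 508) == 1

    def test_observation_just_outside_window_removed(self):
        positions = [500] * 15 + [511] + [100, 220, 340, 460]
        _, retained, removed = end_caller.call_enriched_ends(obs(positions), "TSS")
        assert all(o.position != 511 for o in retained)

    def test_empty_observations(self):
        assert end_caller.call_enriched_ends([], "TSS") == ([], [], [])

    def test_scattered_cloud_called_with_window_support(self):
        """A jittered cloud plus uniform scatter: the dominant site is
        called at the cloud and scatter stays uncalled."""
        rng = np.random.default_rng(8)
        cloud = (500 + np.round(rng.normal(0, 10, size=60))).astype(int)
        scatter = rng.integers(1000, 3000, size=12)
        sites, _, _ = end_caller.call_enriched_ends(
            obs(list(cloud) + list(scatter)), "TES"
        )
        assert len(sites) >= 1
        assert abs(sites[0].position - 500) <= 10
        assert all(abs(s.position - 500) <= 30 for s in sites)

    def test_literal_variant_tests_exact_positions(self):
        positions = [500] * 15 + [100, 220, 340, 460, 900]
        sites, _, _ = end_caller.call_enriched_ends(
            obs(positions), "TSS", window_support=False
        )
        assert [s.position for s in sites] == [500]


class TestFixedWindow:
    def test_two_reads_within_window(self):
        sites, retained, _ = end_caller.fixed_window_ends(obs([100, 115]), "TSS")
        assert len(sites) == 1
        assert sites[0].supporting_reads == 2
        assert sites[0].method == "fixed_window"

    def test_two_reads_too_far_apart(self):
        sites, _, removed = end_caller.fixed_window_ends(obs([100, 150]), "TSS")
        assert sites == [] and len(removed) == 2

    def test_single_read_calls_nothing(self):
        assert end_caller.fixed_window_ends(obs([100]), "TSS")[0] == []

    def test_tes_window_is_wider(self):
        assert len(end_caller.fixed_window_ends(obs([100, 150]), "TES")[0]) == 1

    def test_site_at_support_weighted_mode(self):
        sites, _, _ = end_caller.fixed_window_ends(
            obs([100, 100, 100, 110, 110]), "TSS"
        )
        assert sites[0].position == 100
        assert sites[0].supporting_reads == 5

    def test_tie_breaks_toward_five_prime(self):
        plus, _, _ = end_caller.fixed_window_ends(obs([100, 110]), "TSS", strand="+")
        minus, _, _ = end_caller.fixed_window_ends(obs([100, 110]), "TSS", strand="-")
        assert plus[0].position == 100
        assert minus[0].position == 110


class TestGeneClassification:
    def test_both_sides_called(self):
        calls = end_caller.call_gene_ends(
            obs([100] * 5, kind="TSS"), obs([900] * 5, kind="TES"), "+"
        )
        assert calls.called

    def test_internal_priming_observations_dropped(self):
        tes = [
            EndObservation("g1", f"r{i}", "TES", 900, internal_priming=True)
            for i in range(5)
        ]
        calls = end_caller.call_gene_ends(obs([100] * 5, kind="TSS"), tes, "+")
        assert calls.tes == [] and not calls.called

    def test_single_read_gene_goes_to_rescue(self):
        calls = end_caller.call_gene_ends(
            obs([100], kind="TSS"), obs([900], kind="TES"), "+"
        )
        partition = end_caller.classify_genes([calls])
        assert partition["rescue"] == {"g1"}

    def test_mixed_methods_still_called(self):
        # TSS enriched binomially; TES support too even for enrichment,
        # caught by the fixed window
        tss = obs([100] * 20 + [300, 500, 700, 820, 940], kind="TSS")
        tes = obs([900, 905], kind="TES")
        calls = end_caller.call_gene_ends(tss, tes, "+")
        assert calls.called
        assert {s.method for s in calls.tss} == {"binomial"}
        assert {s.method for s in calls.tes} == {"fixed_window"}
        partition = end_caller.classify_genes([calls])
        assert partition["binomial_called"] == {"g1"}

    def test_fixed_window_only_gene(self):
        calls = end_caller.call_gene_ends(
            obs([100, 104], kind="TSS"), obs([900, 930], kind="TES"), "+"
        )
        partition = end_caller.classify_genes([calls])
        assert partition["fixed_window_called"] == {"g1"}
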