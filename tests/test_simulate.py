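"""Synthetic-data generator: determinism, construction guarantees, labels."""

import collections

import numpy as np
import pytest

from rtdforge import end_caller, sj_filter
from rtdforge.simulate import (
    SimulationConfig,
    simulate_dataset,
    simulate_flnc_reads,
    simulate_genome,
    simulate_sj_tab,
    simulate_tpm,
)


@pytest.fixture(scope="module")
def default_dataset():
    return simulate_dataset(SimulationConfig(seed=21, n_genes=40))


def zero_noise_config(**kw):
    return SimulationConfig(
        truncation_prob_5=0, truncation_prob_3=0, tss_jitter_sd=0,
        tes_jitter_sd=0, junction_shift_rate=0, template_switch_rate=0,
        internal_priming_rate=0, **kw
    )


class TestGenome:
    def test_deterministic(self):
        cfg = SimulationConfig(seed=33, n_genes=10)
        g1, t1 = simulate_genome(cfg)
        g2, t2 = simulate_genome(cfg)
        assert all(g1[c] == g2[c] for c in g1)
        assert len(t1.genes) == 10

    def test_different_seeds_differ(self):
        g1, _ = simulate_genome(SimulationConfig(seed=1, n_genes=5))
        g2, _ = simulate_genome(SimulationConfig(seed=2, n_genes=5))
        assert any(g1[c] != g2[c] for c in g1)

    def test_all_true_introns_canonical(self, default_dataset):
        truth, genome = default_dataset.truth, default_dataset.genome
        for chrom, strand, start, end in truth.true_junctions:
            junction = sj_filter.make_junction(chrom, strand, start, end, genome)
            assert sj_filter.is_canonical(junction)

    def test_true_junctions_never_look_like_template_switch(self, default_dataset):
        truth, genome = default_dataset.truth, default_dataset.genome
        for chrom, strand, start, end in truth.true_junctions:
            junction = sj_filter.make_junction(chrom, strand, start, end, genome)
            _, _, flagged = sj_filter.template_switch_test(junction, genome)
            assert not flagged

    def test_tata_planted_upstream_of_primary_tss(self, default_dataset):
        from rtdforge import motif_scan

        truth, genome = default_dataset.truth, default_dataset.genome
        sites = [
            (g.chrom, g.transcripts[0].five_prime, g.strand)
            for g in truth.genes.values()
        ]
        seqs, _ = motif_scan.extract_flanks(sites, genome)
        profile = motif_scan.profile_motif(
            seqs, motif_scan.MotifSpec("TATA", r"TATA[AT]A[AT]", "TSS")
        )
        pos, density = profile.peak()
        assert pos == -30 and density == 1.0

    def test_internal_priming_decoys_are_a_rich(self, default_dataset):
        truth, genome = default_dataset.truth, default_dataset.genome
        decoys = [g for g in truth.genes.values() if g.ip_decoy is not None]
        assert decoys
        for g in decoys:
            assert end_caller.internal_priming_flag(g.chrom, g.ip_decoy, g.strand, genome)

    def test_true_ends_not_internal_priming_flagged(self, default_dataset):
        truth, genome = default_dataset.truth, default_dataset.genome
        for g in truth.genes.values():
            for pos, _ in g.tes:
                assert not end_caller.internal_priming_flag(g.chrom, pos, g.strand, genome)


class TestReads:
    def test_zero_noise_reads_equal_truth_models(self):
        cfg = zero_noise_config(seed=3, n_genes=15)
        dataset = simulate_dataset(cfg)
        by_tid = {t.transcript_id: t for t in dataset.truth.transcripts}
        for aln in dataset.reads:
            truth_read = dataset.truth.reads[aln.read_id]
            assert truth_read.labels == frozenset()
            assert aln.exon_blocks == by_tid[truth_read.transcript_id].exon_blocks
            assert aln.mismatch_positions == ()

    def test_junction_shift_plants_substitution_in_window(self):
        cfg = SimulationConfig(
            seed=5, n_genes=20, junction_shift_rate=1.0,
            template_switch_rate=0, internal_priming_rate=0,
            truncation_prob_5=0, truncation_prob_3=0,
            tss_jitter_sd=0, tes_jitter_sd=0, exons_per_gene=(2, 4),
        )
        dataset = simulate_dataset(cfg)
        shifted = [
            r for r in dataset.reads
            if "junction_shift" in dataset.truth.reads[r.read_id].labels
        ]
        assert shifted
        for r in shifted:
            assert len(r.mismatch_positions) == 1
            # the substitution sits within 10 nt of one of the read's junctions
            (pos,) = r.mismatch_positions
            assert any(
                start - 10 <= pos < start or end <= pos < end + 10
                for start, end in r.introns
            )

    def test_template_switch_reads_carry_decoy_junction(self):
        cfg = SimulationConfig(
            seed=6, n_genes=20, template_switch_rate=1.0,
            junction_shift_rate=0, internal_priming_rate=0,
            truncation_prob_5=0, truncation_prob_3=0,
            tss_jitter_sd=0, tes_jitter_sd=0, exons_per_gene=(2, 4),
        )
        dataset = simulate_dataset(cfg)
        ts_reads = [
            r for r in dataset.reads
            if "template_switch" in dataset.truth.reads[r.read_id].labels
        ]
        assert ts_reads
        for r in ts_reads:
            gene = dataset.truth.genes[r.read_id.rsplit(".r", 1)[0]]
            assert gene.ts_decoy in r.introns

    def test_internal_priming_reads_stop_at_decoy(self):
        cfg = SimulationConfig(
            seed=7, n_genes=20, internal_priming_rate=1.0,
            junction_shift_rate=0, template_switch_rate=0,
            truncation_prob_5=0, truncation_prob_3=0,
            tss_jitter_sd=0, tes_jitter_sd=0,
        )
        dataset = simulate_dataset(cfg)
        ip_reads = [
            r for r in dataset.reads
            if "internal_priming" in dataset.truth.reads[r.read_id].labels
        ]
        assert ip_reads
        for r in ip_reads:
            gene = dataset.truth.genes[r.read_id.rsplit(".r", 1)[0]]
            assert r.three_prime == gene.ip_decoy

    def test_every_read_has_one_source_transcript(self, default_dataset):
        tids = {t.transcript_id for t in default_dataset.truth.transcripts}
        for aln in default_dataset.reads:
            assert default_dataset.truth.reads[aln.read_id].transcript_id in tids

    def test_read_stream_deterministic(self):
        cfg = SimulationConfig(seed=9, n_genes=10)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        assert [(r.read_id, r.exon_blocks, r.mismatch_positions) for r in a.reads] == [
            (r.read_id, r.exon_blocks, r.mismatch_positions) for r in b.reads
        ]


class TestSjTabAndTpm:
    def test_true_junctions_pass_shortread_filter_without_dropout(self, default_dataset):
        hc = sj_filter.hc_sj_shortread(default_dataset.sj_records, default_dataset.genome)
        assert default_dataset.truth.true_junctions <= hc

    def test_false_junctions_fail_shortread_filter(self, default_dataset):
        hc = sj_filter.hc_sj_shortread(default_dataset.sj_records, default_dataset.genome)
        assert not (default_dataset.truth.false_junctions & hc)

    def test_dropout_removes_records(self):
        cfg = SimulationConfig(seed=4, n_genes=30, sj_dropout=0.5)
        dataset = simulate_dataset(cfg)
        assert len(
            [r for r in dataset.sj_records
             if (r.chrom, r.strand, r.start, r.end) in dataset.truth.true_junctions]
        ) < len(dataset.truth.true_junctions)

    def test_low_expressors_exceed_1tpm_in_one_sample(self, default_dataset):
        truth, tpm = default_dataset.truth, default_dataset.tpm
        low = [g for g in truth.genes.values() if g.low_expressor]
        assert low
        for g in low:
            gene_tpm = tpm.loc[[t.transcript_id for t in g.transcripts]].sum(axis=0)
            assert int((gene_tpm > 1.0).sum()) == 1

    def test_other_genes_expressed_in_two_samples(self, default_dataset):
        truth, tpm = default_dataset.truth, default_dataset.tpm
        for g in truth.genes.values():
            if g.low_expressor:
                continue
            gene_tpm = tpm.loc[[t.transcript_id for t in g.transcripts]].sum(axis=0)
            assert int((gene_tpm > 1.0).sum()) >= 2

    def test_expressed_rows_positive(self, default_dataset):
        assert (default_dataset.tpm.sum(axis=1) > 0).all()
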