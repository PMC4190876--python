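"""Synthetic-world generator: determinism, calibration, construction guarantees."""
import numpy as np
import pytest
from pydantic import ValidationError

import pkdpanel.io as pio
from pkdpanel.simulate import (DeletionEvent, SimConfig, generate_reference,
                               simulate_coverage_matrix, simulate_depth_tracks,
                               simulate_variant_calls)


class TestConfigValidation:
    def test_gene_too_small_for_exon_structure(self):
        with pytest.raises(ValidationError, match="too small"):
            SimConfig(gene_length_bp=500, n_exons=10, exon_length_bp=90,
                      intron_length_bp=100)

    def test_leakage_range_must_stay_below_filter_threshold(self):
        with pytest.raises(ValidationError):
            SimConfig(leakage_fraction_range=(0.05, 0.25))

    def test_divergence_bounds(self):
        with pytest.raises(ValidationError):
            SimConfig(divergence=1.0)

    def test_cds_length_must_be_codon_aligned(self):
        with pytest.raises(ValidationError, match="multiple of 3"):
            SimConfig(n_exons=7, exon_length_bp=100)


class TestReference:
    def test_seed_determinism_byte_identical_outputs(self, small_cfg, tmp_path):
        a = generate_reference(small_cfg)
        b = generate_reference(small_cfg)
        assert a.sequence == b.sequence and a.exons == b.exons
        pio.write_fasta({a.contig: a.sequence}, tmp_path / "a.fa")
        pio.write_fasta({b.contig: b.sequence}, tmp_path / "b.fa")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_zero_divergence_copies_are_identical(self, small_cfg):
        ref = generate_reference(small_cfg.model_copy(update={"divergence": 1e-12}))
        # practically zero divergence: identity 1 for every copy
        assert np.allclose(ref.pseudogene_identities(), 1.0)
        ref0 = generate_reference(small_cfg.model_copy(update={"divergence": 0.0}))
        assert np.allclose(ref0.pseudogene_identities(), 1.0)

    def test_no_pseudogenes_leaves_only_the_gene(self, small_cfg):
        ref = generate_reference(small_cfg.model_copy(update={"n_pseudogenes": 0}))
        assert ref.pseudogene_intervals == []

    def test_identity_calibrated_to_divergence(self):
        cfg = SimConfig(seed=5)
        ref = generate_reference(cfg)
        ids = ref.pseudogene_identities()
        p = 1.0 - cfg.divergence
        L = ref.gene_interval[1] - ref.gene_interval[0]
        se = np.sqrt(p * (1 - p) / (L * cfg.n_pseudogenes))
        assert abs(ids.mean() - p) < 3 * se


class TestVariantCalls:
    def test_zero_leakage_means_no_spurious_calls(self, small_cfg, small_reference):
        cfg = small_cfg.model_copy(update={"leakage_rate": 0.0})
        _, truth = simulate_variant_calls(cfg, small_reference)
        assert truth.spurious_calls == []

    def test_spurious_calls_carry_the_artifact_signature(self, small_cfg, small_reference):
        _, truth = simulate_variant_calls(small_cfg, small_reference)
        assert truth.spurious_calls  # leakage_rate 2.0 over 10 samples
        for s in truth.spurious_calls:
            assert s.alt_fraction < 0.20
        # truth lists are disjoint
        true_keys = {(t.sample_id, t.pos) for t in truth.true_variants}
        spur_keys = {(s.sample_id, s.pos) for s in truth.spurious_calls}
        assert not (true_keys & spur_keys)

    def test_het_fractions_concentrate_at_half(self, small_reference):
        cfg = SimConfig(
            gene_length_bp=2000, n_exons=10, exon_length_bp=90,
            intron_length_bp=100, flank_bp=200, n_samples=40,
            mean_depth=200.0, leakage_rate=0.0, seed=3,
        )
        ref = generate_reference(cfg)
        _, truth = simulate_variant_calls(cfg, ref)
        fr = np.array([t.alt_fraction for t in truth.true_variants])
        ci = 1.96 * np.sqrt(0.25 / 200)  # binomial CI half-width at n=200, p=0.5
        assert (np.abs(fr - 0.5) <= ci).mean() >= 0.80
        assert abs(fr.mean() - 0.5) < 0.03

    def test_true_variants_have_both_strand_support(self, small_cfg, small_reference):
        calls, truth = simulate_variant_calls(small_cfg, small_reference)
        true_keys = {(t.sample_id, t.pos) for t in truth.true_variants}
        for v in calls:
            if (v.sample_id, v.pos) in true_keys:
                assert v.fwd_alt >= 1 and v.rev_alt >= 1
                assert not v.pop_freqs  # pathogenic variants unseen in populations

    def test_determinism(self, small_cfg, small_reference):
        a, _ = simulate_variant_calls(small_cfg, small_reference)
        b, _ = simulate_variant_calls(small_cfg, small_reference)
        assert a == b


class TestCoverageMatrix:
    def test_requires_baseline_cohort_and_targets(self, small_cfg):
        with pytest.raises(ValueError, match=">= 8 samples"):
            simulate_coverage_matrix(small_cfg.model_copy(update={"n_samples": 5}))
        with pytest.raises(ValueError, match=">= 20 targets"):
            simulate_coverage_matrix(small_cfg, targets=[("c", 0, 100)] * 10)

    def test_column_means_track_expected_count(self):
        cfg = SimConfig(seed=2, dropout_exons=())
        m, _ = simulate_coverage_matrix(cfg)
        col_means = m.counts.mean(axis=0)
        assert abs(col_means.mean() / cfg.mean_target_count - 1) < 0.05
        assert np.all(np.abs(col_means / cfg.mean_target_count - 1) < 0.2)

    def test_heterozygous_deletion_halves_counts(self):
        """Poisson-thinning oracle: counts over the span ≈ half the cohort median."""
        cfg = SimConfig(seed=4)
        ev = DeletionEvent("S010", 10, 25, 0.5)
        m, truth = simulate_coverage_matrix(cfg, deletions=[ev])
        assert truth.deletion_events == [ev]
        si = m.samples.index("S010")
        span = slice(10, 26)
        med = np.median(m.counts[:, span], axis=0)
        ratio = m.counts[si, span] / med
        assert 0.4 < ratio.mean() < 0.6

    def test_dropout_targets_near_zero_in_every_sample(self):
        cfg = SimConfig(seed=6, dropout_exons=(0,))
        m, _ = simulate_coverage_matrix(cfg)
        assert (m.counts[:, 0] < 0.05 * cfg.mean_target_count).all()

    def test_invalid_deletion_span_rejected(self, small_cfg):
        with pytest.raises(ValueError, match="outside target range"):
            simulate_coverage_matrix(
                SimConfig(seed=0), deletions=[DeletionEvent("S001", 90, 150, 0.5)])


def test_depth_tracks_reflect_dropout(small_cfg, small_reference):
    tracks = simulate_depth_tracks(small_cfg, small_reference.targets)
    assert len(tracks) == small_cfg.n_samples
    for tr in tracks:
        d0 = tr.depths[0]
        rest = np.concatenate(tr.depths[1:])
        assert d0.mean() < 0.05 * rest.mean()
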