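"""RPKM/ZRPKM/SVD normalization and contiguous-target CNV calling."""
import numpy as np
import pytest

from pkdpanel.cnv import (CnvCall, CoverageMatrix, ZrpkmMatrix, call_cnvs,
                          compute_rpkm, compute_zrpkm, detect_deletions,
                          svd_denoise)
from pkdpanel.simulate import DeletionEvent, SimConfig, simulate_coverage_matrix


def matrix_from(counts, lengths=None, totals=None):
    counts = np.asarray(counts)
    n_s, n_t = counts.shape
    lengths = lengths or [1000] * n_t
    targets = []
    pos = 0
    for L in lengths:
        targets.append(("chr1", pos, pos + L))
        pos += L + 10
    return CoverageMatrix(samples=[f"S{i}" for i in range(n_s)],
                          targets=targets, counts=counts, totals=totals)


class TestRpkm:
    def test_textbook_value(self):
        m = matrix_from([[100]], lengths=[1000], totals=np.array([1e6]))
        r = compute_rpkm(m)
        assert r.values[0, 0] == pytest.approx(100.0)

    def test_zero_counts_give_zero(self):
        m = matrix_from([[0, 5]], totals=np.array([1e6]))
        assert compute_rpkm(m).values[0, 0] == 0.0

    def test_library_size_scale_invariance(self):
        base = np.array([[10, 20, 30], [40, 50, 60]])
        m1 = matrix_from(base)
        m2 = matrix_from(base * np.array([[3], [7]]))
        np.testing.assert_allclose(compute_rpkm(m1).values, compute_rpkm(m2).values)

    def test_zero_total_sample_excluded_with_warning(self):
        counts = np.vstack([np.zeros(3, dtype=int), np.ones((2, 3), dtype=int)])
        m = matrix_from(counts)
        with pytest.warns(UserWarning, match="zero mapped reads"):
            r = compute_rpkm(m)
        assert r.values.shape == (2, 3) and "S0" not in r.samples


class TestZrpkm:
    def _rpkm(self, values):
        values = np.asarray(values, dtype=float)
        n_s, n_t = values.shape
        return ZrpkmMatrix(samples=[f"S{i}" for i in range(n_s)],
                           targets=[("c", i, i + 1) for i in range(n_t)],
                           values=values, stage="rpkm")

    def test_needs_baseline_cohort(self):
        with pytest.raises(ValueError, match=">= 8 samples"):
            compute_zrpkm(self._rpkm(np.ones((3, 4))))

    def test_identical_rows_are_masked_not_divided(self):
        z = compute_zrpkm(self._rpkm(np.ones((9, 4))))
        assert z.masked.all()
        assert np.allclose(z.values, 0.0)

    def test_median_zero_and_low_sample_negative(self):
        rng = np.random.default_rng(0)
        v = rng.normal(100, 5, size=(20, 6))
        v[3, 2] = 50  # one sample at half depth on one target
        z = compute_zrpkm(self._rpkm(v))
        assert np.allclose(np.median(z.values, axis=0), 0.0, atol=0.3)
        assert z.values[3, 2] < -3


class TestSvd:
    def _z(self, values):
        values = np.asarray(values, dtype=float)
        n_s, n_t = values.shape
        return ZrpkmMatrix(samples=[f"S{i}" for i in range(n_s)],
                           targets=[("c", i, i + 1) for i in range(n_t)],
                           values=values, stage="zrpkm")

    def test_k0_is_identity(self):
        rng = np.random.default_rng(1)
        z = self._z(rng.normal(size=(10, 15)))
        np.testing.assert_array_equal(svd_denoise(z, 0).values, z.values)

    def test_rank1_annihilated_by_k1(self):
        u = np.arange(1, 9, dtype=float)[:, None]
        v = np.arange(1, 13, dtype=float)[None, :]
        z = self._z(u @ v)
        assert np.abs(svd_denoise(z, 1).values).max() < 1e-8

    def test_frobenius_norm_nonincreasing_in_k(self):
        rng = np.random.default_rng(2)
        z = self._z(rng.normal(size=(12, 30)))
        norms = [np.linalg.norm(svd_denoise(z, k).values) for k in range(6)]
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_invalid_k_rejected(self):
        z = self._z(np.zeros((8, 10)))
        with pytest.raises(ValueError):
            svd_denoise(z, -1)
        with pytest.raises(ValueError):
            svd_denoise(z, 8)


class TestCalling:
    def _svdz(self, values, masked=None):
        values = np.asarray(values, dtype=float)
        n_s, n_t = values.shape
        return ZrpkmMatrix(samples=[f"S{i}" for i in range(n_s)],
                           targets=[("c", i, i + 1) for i in range(n_t)],
                           values=values, stage="svd_zrpkm",
                           masked=masked)

    def test_all_zero_matrix_yields_no_calls(self):
        assert call_cnvs(self._svdz(np.zeros((9, 25)))) == []

    def test_run_length_and_direction(self):
        v = np.zeros((8, 20))
        v[2, 5:9] = -2.0   # deletion run of 4
        v[3, 12] = -9.0    # single target: below min_targets
        v[4, 14:16] = 2.0  # duplication run of 2
        calls = call_cnvs(self._svdz(v))
        assert calls == [
            CnvCall("S2", 5, 8, "deletion", -2.0),
            CnvCall("S4", 14, 15, "duplication", 2.0),
        ]

    def test_masked_targets_break_runs(self):
        v = np.zeros((8, 10))
        v[1, 3:7] = -3.0
        masked = np.zeros(10, dtype=bool)
        masked[5] = True
        calls = call_cnvs(self._svdz(v, masked=masked))
        assert [(c.first_target, c.last_target) for c in calls] == [(3, 4)]


class TestEndToEnd:
    def test_spiked_deletion_recovered_with_exact_span(self):
        cfg = SimConfig(seed=11)
        m, _ = simulate_coverage_matrix(
            cfg, deletions=[DeletionEvent("S007", 10, 25, 0.5)])
        calls, z = detect_deletions(m)
        assert len(calls) == 1
        c = calls[0]
        assert c.sample_id == "S007" and c.direction == "deletion"
        assert abs(c.first_target - 10) <= 1 and abs(c.last_target - 25) <= 1
        assert z.stage == "svd_zrpkm" and z.removed_components == 3

    def test_sample_permutation_equivariance(self):
        cfg = SimConfig(seed=12)
        m, _ = simulate_coverage_matrix(
            cfg, deletions=[DeletionEvent("S003", 30, 45, 0.5)])
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(m.samples))
        mp = CoverageMatrix(samples=[m.samples[i] for i in perm],
                            targets=m.targets, counts=m.counts[perm],
                            totals=m.totals[perm])
        calls_a, _ = detect_deletions(m)
        calls_b, _ = detect_deletions(mp)
        key = lambda c: (c.sample_id, c.first_target, c.last_target, c.direction)
        assert sorted(map(key, calls_a)) == sorted(map(key, calls_b))
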