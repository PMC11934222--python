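"""CCG computation, normalization baselines, and the DCE statistic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from statesync.ccg import (CCG, UP_ONLY, compute_ccg, compute_dce,
                           jitter_baseline, jitter_spike_train, normalize_ccg,
                           pair_dce, smooth_triangular, triangular_baseline)
from statesync.core import EpochSet, SpikeTrain

from conftest import poisson_train


def make_ccg(counts, bin_width=0.005):
    counts = np.asarray(counts, dtype=float)
    half = (counts.size - 1) // 2
    grid = np.arange(-half, half + 1) * bin_width
    return CCG(("x", "y"), grid, counts, bin_width, half * bin_width, 1)


class TestComputeCCG:
    def test_direct_enumeration(self):
        a = SpikeTrain("a", np.array([1.0, 2.0]), 0, 3)
        b = SpikeTrain("b", np.array([1.0, 2.0]), 0, 3)
        ep = EpochSet.from_tuples([(0, 3, "NREM")])
        c = compute_ccg(a, b, ep, "NREM", 0.005, 1.0)
        lag = c.lag_centers
        assert c.counts[lag == 0.0] == 2          # (1,1) and (2,2)
        assert c.counts[np.isclose(lag, 1.0)] == 1   # (1,2)
        assert c.counts[np.isclose(lag, -1.0)] == 1  # (2,1)
        assert c.total == 4

    def test_only_same_epoch_pairs_counted(self):
        a = SpikeTrain("a", np.array([0.5]), 0, 20)
        b = SpikeTrain("b", np.array([10.5]), 0, 20)
        ep = EpochSet.from_tuples([(0, 1, "NREM"), (10, 11, "NREM")])
        c = compute_ccg(a, b, ep, "NREM")
        assert c.total == 0

    def test_poisson_coincidence_rate(self, rng, single_nrem_epoch):
        a = poisson_train("a", 2.0, 1000.0, rng)
        b = poisson_train("b", 2.0, 1000.0, rng)
        c = compute_ccg(a, b, single_nrem_epoch, "NREM")
        expected = 2.0 * 2.0 * 1000.0 * 0.005
        assert c.counts.mean() == pytest.approx(expected, rel=0.1)

    def test_missing_label_errors(self, single_nrem_epoch):
        a = SpikeTrain("a", np.array([1.0]), 0, 10)
        with pytest.raises(ValueError, match="no epochs"):
            compute_ccg(a, a, single_nrem_epoch, "REM")

    def test_no_spikes_warns_and_zeroes(self, single_nrem_epoch):
        a = SpikeTrain("a", np.empty(0), 0, 1000)
        b = SpikeTrain("b", np.array([5.0]), 0, 1000)
        with pytest.warns(UserWarning, match="no spikes"):
            c = compute_ccg(a, b, single_nrem_epoch, "NREM")
        assert c.empty and c.total == 0

    def test_bad_lag_grid_rejected(self, single_nrem_epoch):
        a = SpikeTrain("a", np.array([1.0]), 0, 1000)
        with pytest.raises(ValueError, match="multiple"):
            compute_ccg(a, a, single_nrem_epoch, "NREM", 0.003, 1.0)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.floats(0.0, 99.9), min_size=1, max_size=60),
           st.lists(st.floats(0.0, 99.9), min_size=1, max_size=60))
    def test_reversal_symmetry(self, ta, tb):
        """compute_ccg(a, b) reversed in lag equals compute_ccg(b, a)."""
        ep = EpochSet.from_tuples([(0, 100, "NREM")])
        a = SpikeTrain("a", np.sort(ta), 0, 100)
        b = SpikeTrain("b", np.sort(tb), 0, 100)
        cab = compute_ccg(a, b, ep, "NREM", 0.01, 0.5)
        cba = compute_ccg(b, a, ep, "NREM", 0.01, 0.5)
        assert np.array_equal(cab.counts, cba.counts[::-1])


class TestSmoothTriangular:
    def test_flat_is_invariant(self):
        c = make_ccg(np.full(401, 7.0))
        sm = smooth_triangular(c)
        assert np.allclose(sm.counts, 7.0)

    def test_impulse_becomes_unit_area_triangle(self):
        counts = np.zeros(401)
        counts[200] = 5.0
        sm = smooth_triangular(make_ccg(counts))
        assert sm.counts.argmax() == 200
        assert sm.counts.sum() == pytest.approx(5.0)
        assert np.allclose(sm.counts, sm.counts[::-1])

    def test_matches_bruteforce_convolution(self, rng):
        counts = rng.poisson(30.0, size=401).astype(float)
        sm = smooth_triangular(make_ccg(counts), window=0.1)
        n = 21  # 0.1 s / 5 ms rounded to odd
        k = 1.0 - np.abs(np.arange(n) - n // 2) / ((n + 1) / 2)
        k /= k.sum()
        expected = np.empty_like(counts)
        for i in range(counts.size):
            acc = wsum = 0.0
            for j in range(n):
                src = i + j - n // 2
                if 0 <= src < counts.size:
                    acc += k[j] * counts[src]
                    wsum += k[j]
            expected[i] = acc / wsum
        assert np.allclose(sm.counts, expected)

    def test_window_narrower_than_two_bins_rejected(self):
        with pytest.raises(ValueError):
            smooth_triangular(make_ccg(np.ones(401)), window=0.004)


class TestJitter:
    def test_spike_stays_in_its_partition(self, rng):
        ep = EpochSet.from_tuples([(0.0, 2.0, "NREM")])
        tr = SpikeTrain("a", np.array([0.30, 1.74]), 0, 2)
        for _ in range(20):
            j = jitter_spike_train(tr, ep, "NREM", 0.5, rng)
            assert 0.0 <= j.times.min() < 0.5
            assert 1.5 <= j.times.max() < 2.0

    def test_independent_pair_preserved_in_expectation(self, rng,
                                                       single_nrem_epoch):
        a = poisson_train("a", 4.0, 1000.0, rng)
        b = poisson_train("b", 4.0, 1000.0, rng)
        raw = compute_ccg(a, b, single_nrem_epoch, "NREM")
        jit = jitter_baseline(a, b, single_nrem_epoch, "NREM", reps=20,
                              seed=3)
        assert jit.counts.mean() == pytest.approx(raw.counts.mean(), rel=0.05)

    def test_synchronous_peak_is_flattened(self, rng, single_nrem_epoch):
        base = np.sort(rng.uniform(0, 1000, 3000))
        a = SpikeTrain("a", base, 0, 1000)
        b = SpikeTrain("b", np.sort(base + rng.normal(0, 0.003, base.size)),
                       0, 1001)
        raw = compute_ccg(a, b, single_nrem_epoch, "NREM")
        jit = jitter_baseline(a, b, single_nrem_epoch, "NREM", reps=5, seed=4)
        mid = np.abs(raw.lag_centers) <= 0.01
        assert jit.counts[mid].max() < 0.2 * raw.counts[mid].max()


class TestNormalize:
    def test_equal_ccgs_give_zero(self):
        c = make_ccg(np.arange(401, dtype=float))
        n = normalize_ccg(c, c)
        assert np.allclose(n.values, 0.0)

    def test_log_ratio_scale(self):
        base = make_ccg(np.full(401, 5000.0))
        raw = make_ccg(np.e * np.full(401, 5000.0))
        n = normalize_ccg(raw, base)
        assert np.allclose(n.values, 1.0, atol=1e-3)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="lag grid"):
            normalize_ccg(make_ccg(np.ones(401)), make_ccg(np.ones(801)))


class TestDCE:
    def test_flat_normalized_ccg_is_null(self):
        c = make_ccg(np.full(401, 10.0))
        res = compute_dce(normalize_ccg(c, smooth_triangular(c)))
        assert res.dce == pytest.approx(0.0, abs=1e-9)
        assert not res.significant
        assert res.effective_dce == 0.0

    def test_constructed_center_signal(self):
        c = make_ccg(np.full(401, 10.0))
        nccg = normalize_ccg(c, c)
        nccg.values[np.abs(nccg.lag_centers) <= 0.125] = 1.0
        res = compute_dce(nccg)
        assert res.dce == pytest.approx(1.0)
        assert res.significant

    def test_antiphase_pair_trough(self, antiphase_recording):
        rec = antiphase_recording
        by_id = {t.unit_id: t for t in rec.trains}
        ua, ub = rec.truth.all_pairs[0]
        _, res = pair_dce(by_id[ua], by_id[ub], rec.states, "NREM")
        assert res.dce < 0 and res.significant

    def test_dce_invariant_under_pair_swap(self, antiphase_recording):
        rec = antiphase_recording
        by_id = {t.unit_id: t for t in rec.trains}
        ua, ub = rec.truth.all_pairs[1]
        _, r1 = pair_dce(by_id[ua], by_id[ub], rec.states, "NREM")
        _, r2 = pair_dce(by_id[ub], by_id[ua], rec.states, "NREM")
        assert r1.dce == pytest.approx(r2.dce)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_up_only_needs_two_second_lags(self):
        c = make_ccg(np.full(401, 10.0))  # +-1 s only
        with pytest.raises(ValueError, match="2 s"):
            compute_dce(normalize_ccg(c, c), variant=UP_ONLY)

    def test_up_only_edge_windows(self):
        c = make_ccg(np.full(801, 10.0))  # +-2 s
        nccg = normalize_ccg(c, c)
        nccg.values[np.abs(nccg.lag_centers) >= 1.0] = -0.5
        res = compute_dce(nccg, variant=UP_ONLY)
        assert res.dce == pytest.approx(0.5)

    def test_extended_baseline_matches_direct_raw(self, rng,
                                                  single_nrem_epoch):
        """The edge-unbiased baseline leaves the raw CCG itself unchanged."""
        a = poisson_train("a", 3.0, 1000.0, rng)
        b = poisson_train("b", 3.0, 1000.0, rng)
        raw_direct = compute_ccg(a, b, single_nrem_epoch, "NREM")
        raw_crop, base = triangular_baseline(a, b, single_nrem_epoch, "NREM")
        assert np.array_equal(raw_direct.counts, raw_crop.counts)
        assert base.counts.size == raw_crop.counts.size
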