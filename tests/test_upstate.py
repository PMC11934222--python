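"""UP-state analyses: detection, UP-only DCE, scrambling, profiles,
resimulation and timing metrics."""

import numpy as np
import pytest

from statesync.ccg import compute_ccg
from statesync.core import EpochSet, SpikeTrain
from statesync.synth import (ANTIPHASE, BURSTY_ANTIPHASE, COACTIVE,
                             INDEPENDENT, SyntheticConfig,
                             generate_recording)
from statesync.upstate import (UpProfile, detect_up_down,
                               dce_null_from_simulation, scramble_up_next,
                               scrambled_up_dce, simulate_profile_pair,
                               up_only_dce, up_spike_profile,
                               up_timing_metrics)


def jaccard_intervals(a, b, t_end, dt=0.005):
    grid = np.zeros(int(t_end / dt), dtype=bool)
    ga = grid.copy()
    for s, e in a:
        ga[int(s / dt):int(e / dt)] = True
    gb = grid.copy()
    for s, e in b:
        gb[int(s / dt):int(e / dt)] = True
    return (ga & gb).sum() / max(1, (ga | gb).sum())


class TestDetection:
    def test_recovers_generator_down_states(self):
        config = SyntheticConfig(
            duration_h=0.5, n_units=20, seed=5,
            down_median_s=0.15, down_range=(0.08, 0.5),
            class_fractions={INDEPENDENT: 1.0, COACTIVE: 0.0,
                             ANTIPHASE: 0.0, BURSTY_ANTIPHASE: 0.0})
        rec = generate_recording(config, seed=5)
        det = detect_up_down(rec.trains, rec.states)
        s_true, e_true = rec.updown.select("UP")
        s_det, e_det = det.select("UP")
        j = jaccard_intervals(zip(s_true, e_true), zip(s_det, e_det),
                              rec.config.duration_s)
        assert j >= 0.9

    def test_constant_rate_population_has_no_downs(self):
        rng = np.random.default_rng(77)
        trains = [SpikeTrain(f"u{i}",
                             np.sort(rng.uniform(0, 300,
                                                 rng.poisson(300 * 20.0))),
                             0, 300) for i in range(10)]
        states = EpochSet.from_tuples([(0, 300, "NREM")])
        det = detect_up_down(trains, states)
        assert det.total_duration("DOWN") == 0.0

    def test_requires_nrem(self, rng):
        tr = [SpikeTrain("a", np.array([1.0]), 0, 10)]
        with pytest.raises(ValueError):
            detect_up_down(tr, EpochSet.from_tuples([(0, 10, "WAKE")]))


class TestUpOnlyDCE:
    def test_down_spikes_never_counted(self, antiphase_recording):
        """Deleting every DOWN/inter-UP spike leaves the UP-only CCG
        unchanged."""
        rec = antiphase_recording
        by_id = {t.unit_id: t for t in rec.trains}
        ua, ub = rec.truth.all_pairs[0]
        a, b = by_id[ua], by_id[ub]
        s, e = rec.updown.select("UP")
        a_up = SpikeTrain(ua, a.restrict(s, e), a.t_start, a.t_end)
        b_up = SpikeTrain(ub, b.restrict(s, e), b.t_start, b.t_end)
        c1 = compute_ccg(a, b, rec.updown, "UP", 0.005, 2.0)
        c2 = compute_ccg(a_up, b_up, rec.updown, "UP", 0.005, 2.0)
        assert np.array_equal(c1.counts, c2.counts)

    def test_antiphase_up_only_trough(self, antiphase_recording):
        rec = antiphase_recording
        by_id = {t.unit_id: t for t in rec.trains}
        ua, ub = rec.truth.all_pairs[0]
        _, res = up_only_dce(by_id[ua], by_id[ub], rec.updown)
        assert res.dce < 0 and res.significant

    def test_trim_to_full_durations_is_identity(self, antiphase_recording):
        rec = antiphase_recording
        by_id = {t.unit_id: t for t in rec.trains}
        ua, ub = rec.truth.all_pairs[0]
        s, e = rec.updown.select("UP")
        _, r1 = up_only_dce(by_id[ua], by_id[ub], rec.updown)
        _, r2 = up_only_dce(by_id[ua], by_id[ub], rec.updown, trim_to=e - s)
        assert r1.dce == pytest.approx(r2.dce)


class TestScrambling:
    def test_identical_patterns_are_shift_invariant(self):
        """Identical per-UP patterns in equal-duration UPs: scrambling is a
        no-op for the CCG."""
        ups = EpochSet.from_tuples([(10.0 * k, 10.0 * k + 2.0, "UP")
                                    for k in range(20)])
        pat = np.array([0.2, 0.9, 1.5])
        ta = np.concatenate([10.0 * k + pat for k in range(20)])
        tb = np.concatenate([10.0 * k + pat + 0.1 for k in range(20)])
        a = SpikeTrain("a", ta, 0, 200)
        b = SpikeTrain("b", tb, 0, 200)
        a_sh, trimmed = scramble_up_next(a, ups)
        c_orig = compute_ccg(a, b, trimmed, "UP", 0.005, 2.0)
        c_scr = compute_ccg(a_sh, b, trimmed, "UP", 0.005, 2.0)
        assert np.array_equal(c_orig.counts, c_scr.counts)

    def test_partner_spike_count_preserved_in_trimmed_ups(self,
                                                          antiphase_recording):
        rec = antiphase_recording
        by_id = {t.unit_id: t for t in rec.trains}
        ua, ub = rec.truth.all_pairs[0]
        _, trimmed = scramble_up_next(by_id[ua], rec.updown)
        s, e = trimmed.select("UP")
        n_direct = by_id[ub].restrict(s, e).size
        assert n_direct > 0  # unshifted partner unchanged apart from trimming

    def test_needs_two_ups(self):
        a = SpikeTrain("a", np.array([0.5]), 0, 10)
        with pytest.raises(ValueError):
            scramble_up_next(a, EpochSet.from_tuples([(0, 1, "UP")]))

    def test_destroys_antiphase_troughs(self, antiphase_recording):
        rec = antiphase_recording
        by_id = {t.unit_id: t for t in rec.trains}
        flipped = 0
        total = 0
        for ua, ub in rec.truth.all_pairs:
            orig, scram = scrambled_up_dce(by_id[ua], by_id[ub], rec.updown)
            if orig.significant and orig.dce < 0:
                total += 1
                flipped += scram.effective_dce >= 0
        assert total >= 3
        assert flipped / total >= 0.9


class TestProfiles:
    def test_single_onset_spike_profile(self):
        ups = EpochSet.from_tuples([(5.0 * k, 5.0 * k + 1.0, "UP")
                                    for k in range(10)])
        tr = SpikeTrain("a", np.array([5.0 * k + 1e-4 for k in range(10)]),
                        0, 50)
        prof = up_spike_profile(tr, ups)
        assert prof.bin_probs[0] == pytest.approx(1.0)
        assert prof.mean_rate_up == pytest.approx(1.0)

    def test_uniform_firing_is_flat(self):
        rng = np.random.default_rng(88)
        ups = EpochSet.from_tuples([(3.0 * k, 3.0 * k + 2.0, "UP")
                                    for k in range(300)])
        s, e = ups.select("UP")
        times = np.sort(np.concatenate(
            [np.sort(rng.uniform(a, b, 20)) for a, b in zip(s, e)]))
        prof = up_spike_profile(SpikeTrain("a", times, 0, 1000), ups)
        assert np.allclose(prof.bin_probs, 0.02, atol=0.006)

    def test_early_bias_recovered(self):
        config = SyntheticConfig(
            duration_h=0.25, n_units=2, seed=9,
            profile_a_range=(1.0, 1.0), profile_b_range=(6.0, 6.0),
            class_fractions={INDEPENDENT: 1.0, COACTIVE: 0.0,
                             ANTIPHASE: 0.0, BURSTY_ANTIPHASE: 0.0})
        rec = generate_recording(config, seed=9)
        prof = up_spike_profile(rec.trains[0], rec.updown)
        assert prof.bin_probs.argmax() < 5  # peak in the first decile

    def test_no_spikes_rejected(self):
        ups = EpochSet.from_tuples([(0, 1, "UP")])
        with pytest.raises(ValueError):
            up_spike_profile(SpikeTrain("a", np.empty(0), 0, 1), ups)

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            UpProfile("a", np.ones(50), 1.0)  # does not sum to 1


class TestSimulation:
    def test_onset_mass_stays_in_first_bins(self):
        probs = np.zeros(50)
        probs[0] = 1.0
        prof = UpProfile("a", probs, 5.0)
        durations = [("UP", 2.0), ("DOWN", 0.2)] * 50
        a, b, ep = simulate_profile_pair(prof, prof, durations, seed=1)
        s, _ = ep.select("UP")
        for t in (a, b):
            rel = t.times - s[np.searchsorted(s, t.times, "right") - 1]
            assert rel.max() <= 0.04 + 1e-9  # first 2% of a 2 s UP

    def test_rate_preserved_in_expectation(self):
        prof = UpProfile("a", np.full(50, 0.02), 4.0)
        durations = [("UP", 1.0), ("DOWN", 0.1)] * 200
        counts = []
        for seed in range(30):
            a, _, _ = simulate_profile_pair(prof, prof, durations, seed=seed)
            counts.append(a.n_spikes)
        assert np.mean(counts) == pytest.approx(4.0 * 200.0, rel=0.05)

    def test_mean_preserving_profile_roundtrip(self):
        rng = np.random.default_rng(3)
        probs = rng.dirichlet(np.full(50, 2.0))
        prof = UpProfile("a", probs, 6.0)
        durations = [("UP", 1.5), ("DOWN", 0.1)] * 2000
        a, _, ep = simulate_profile_pair(prof, prof, durations, seed=4)
        back = up_spike_profile(a, ep)
        assert np.abs(back.bin_probs - probs).sum() < 0.05

    def test_null_z_for_matched_observation(self):
        prof = UpProfile("a", np.full(50, 0.02), 5.0)
        durations = [("UP", 1.0), ("DOWN", 0.1)] * 300
        mu, sd, z, p, vals = dce_null_from_simulation(
            prof, prof, durations, observed_dce=None or 0.0, n_sims=30,
            seed=2)
        # an observation at the null mean would give z = 0, p = 1
        assert abs((mu - mu) / sd) == 0.0
        assert vals.size == 30 and sd > 0


class TestTimingMetrics:
    def test_identical_trains_give_zero(self):
        ups = EpochSet.from_tuples([(2.0 * k, 2.0 * k + 1.0, "UP")
                                    for k in range(15)])
        t = np.concatenate([[2.0 * k + 0.1, 2.0 * k + 0.5]
                            for k in range(15)])
        a = SpikeTrain("a", t, 0, 30)
        m = up_timing_metrics(a, a, ups)
        assert m.mean_diff_first == 0 and m.sd_diff_first == 0
        assert m.mean_diff_mean == 0 and m.sd_diff_mean == 0
        assert m.n_up_states_used == 15 and not m.flagged

    def test_constant_lead_measured_exactly(self):
        ups = EpochSet.from_tuples([(2.0 * k, 2.0 * k + 1.0, "UP")
                                    for k in range(12)])
        ta = np.array([2.0 * k + 0.10 for k in range(12)])
        tb = np.array([2.0 * k + 0.15 for k in range(12)])
        m = up_timing_metrics(SpikeTrain("a", ta, 0, 30),
                              SpikeTrain("b", tb, 0, 30), ups)
        assert m.mean_diff_first == pytest.approx(-0.05)
        assert m.sd_diff_first == pytest.approx(0.0, abs=1e-12)

    def test_few_ups_flagged(self):
        ups = EpochSet.from_tuples([(0, 1, "UP"), (2, 3, "UP")])
        a = SpikeTrain("a", np.array([0.1, 2.1]), 0, 5)
        m = up_timing_metrics(a, a, ups)
        assert m.flagged and m.n_up_states_used == 2
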