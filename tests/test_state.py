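"""Population state pipeline: DCE tables, summaries, downsampling."""

import numpy as np
import pandas as pd
import pytest

from statesync.core import EpochSet
from statesync.state import (StateSynchrony, compare_abs_dce,
                             downsample_matched_dce, proportion_summary,
                             state_dce_table, state_specificity_crosstab,
                             _select_epochs_to_duration)

from conftest import poisson_train


def table_from_rows(rows):
    return pd.DataFrame(rows, columns=["unit_a", "unit_b", "state", "dce",
                                       "p", "significant"])


@pytest.fixture(scope="module")
def three_trains(rng):
    return [poisson_train(f"u{i}", 3.0, 600.0, rng) for i in range(3)]


class TestStateDCETable:
    def test_row_counting(self, three_trains):
        states = EpochSet.from_tuples([(0, 300, "NREM"), (300, 600, "WAKE")])
        t = state_dce_table(three_trains, states)
        assert len(t) == 6  # 3 pairs x 2 states
        assert set(t["state"]) == {"NREM", "WAKE"}

    def test_single_state_delegates_to_pair_dce(self, three_trains):
        from statesync.ccg import pair_dce
        states = EpochSet.from_tuples([(0, 600, "NREM")])
        t = state_dce_table(three_trains, states)
        _, r = pair_dce(three_trains[0], three_trains[1], states, "NREM")
        row = t[(t.unit_a == "u0") & (t.unit_b == "u1")].iloc[0]
        assert row.dce == pytest.approx(r.dce)
        assert row.significant == r.significant

    def test_fewer_than_two_trains_rejected(self, three_trains):
        states = EpochSet.from_tuples([(0, 600, "NREM")])
        with pytest.raises(ValueError):
            state_dce_table(three_trains[:1], states)

    def test_model_results_roundtrip(self, three_trains):
        states = EpochSet.from_tuples([(0, 300, "NREM"), (300, 600, "WAKE")])
        res = StateSynchrony(three_trains, states).fit()
        assert len(res.table) == 6
        assert "DCE" in res.summary()
        mat, pairs, lag = res.stacked("NREM", significant_only=False)
        assert mat.shape[0] == len(pairs)


class TestProportionSummary:
    def test_percentage_arithmetic(self):
        rows = [(f"a{i}", f"b{i}", "NREM", -0.5 if i < 4 else 0.0,
                 1e-6 if i < 4 else 0.5, i < 4) for i in range(100)]
        ps = proportion_summary(table_from_rows(rows))
        assert ps.loc["NREM", "trough_pct"] == pytest.approx(4.0)
        assert ps.loc["NREM", "peak_pct"] == 0.0
        assert ps.loc["NREM", "n_pairs"] == 100

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            proportion_summary(table_from_rows([]))

    def test_matches_row_level_recount(self, mixed_recording):
        rec = mixed_recording
        t = state_dce_table(rec.trains, rec.states,
                            pairs=rec.truth.all_pairs)
        ps = proportion_summary(t)
        for state in ps.index:
            sub = t[t.state == state]
            n_neg = ((sub.significant) & (sub.dce < 0)).sum()
            assert ps.loc[state, "trough_pct"] == pytest.approx(
                100.0 * n_neg / len(sub))


class TestSpecificityCrosstab:
    def test_definition_on_constructed_table(self):
        rows = [("a", "b", "NREM", -0.4, 1e-6, True),
                ("a", "b", "WAKE", 0.0, 0.9, False),
                ("c", "d", "NREM", -0.2, 1e-6, True),
                ("c", "d", "WAKE", -0.3, 1e-6, True)]
        ct = state_specificity_crosstab(table_from_rows(rows))
        # one of two pairs negative-in-NREM with zero-in-WAKE
        assert ct.loc["NREM", "WAKE"] == pytest.approx(50.0)
        # c,d negative in both: contributes to neither ordered cell
        assert ct.loc["WAKE", "NREM"] == pytest.approx(0.0)

    def test_no_significance_gives_zeros(self):
        rows = [("a", "b", s, 0.1, 0.5, False) for s in ("NREM", "WAKE")]
        ct = state_specificity_crosstab(table_from_rows(rows))
        assert (ct.fillna(0).to_numpy() == 0).all()

    def test_single_state_rejected(self):
        rows = [("a", "b", "NREM", -0.4, 1e-6, True)]
        with pytest.raises(ValueError):
            state_specificity_crosstab(table_from_rows(rows))


class TestCompareAbsDCE:
    def test_identical_magnitudes_not_significant(self):
        rows = []
        for i in range(10):
            for s in ("NREM", "WAKE", "REM"):
                rows.append((f"a{i}", f"b{i}", s, 0.3 + 0.01 * i, 1e-6, True))
        rep = compare_abs_dce(table_from_rows(rows))
        assert all(rep.pairwise["p"] > 0.9)

    def test_scaled_state_detected(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(40):
            base = 0.2 + 0.05 * rng.random()
            rows.append((f"a{i}", f"b{i}", "NREM", 2 * base, 1e-6, True))
            rows.append((f"a{i}", f"b{i}", "WAKE", base, 1e-6, True))
            rows.append((f"a{i}", f"b{i}", "REM", base, 1e-6, True))
        rep = compare_abs_dce(table_from_rows(rows))
        pw = rep.pairwise.set_index(["state_a", "state_b"])["p"]
        assert pw[("NREM", "WAKE")] < 0.01
        assert pw[("NREM", "REM")] < 0.01
        assert pw[("WAKE", "REM")] > 0.05

    def test_empty_selection_returns_empty_report(self):
        rows = [("a", "b", s, 0.1, 0.5, False) for s in ("NREM", "WAKE")]
        rep = compare_abs_dce(table_from_rows(rows))
        assert rep.n_pairs == 0 and rep.pairwise.empty


class TestDownsampling:
    def test_epoch_selection_stopping_rule(self):
        rng = np.random.default_rng(1)
        starts = np.arange(0, 1000, 100.0)
        ends = starts + 80.0
        s, e = _select_epochs_to_duration(starts, ends, 200.0, rng)
        total = np.sum(e - s)
        assert 200.0 <= total <= 200.0 + 80.0  # overshoot < one epoch

    def test_never_increases_duration_or_spikes(self, mixed_recording):
        rec = mixed_recording
        trains = rec.trains[:4]
        pairs = [(trains[0].unit_id, trains[1].unit_id)]
        t = downsample_matched_dce(trains, rec.states, reps=2, seed=5,
                                   pairs=pairs)
        assert set(t["state"]) <= {"NREM", "WAKE", "REM"}
        assert len(t) == len(pairs) * t["state"].nunique()

    def test_antiphase_direction_survives_downsampling(self,
                                                       antiphase_recording):
        rec = antiphase_recording
        trains = [t for t in rec.trains
                  if t.unit_id in set(sum(map(list,
                                              rec.truth.all_pairs[:3]), []))]
        t = downsample_matched_dce(trains, rec.states, reps=2, seed=7,
                                   pairs=rec.truth.all_pairs[:3])
        wide = t.pivot(index=["unit_a", "unit_b"], columns="state",
                       values="dce")
        assert (wide["NREM"] < wide["WAKE"]).all()
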