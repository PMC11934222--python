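"""Per-state population DCE analysis.

`StateSynchrony` is the modelling entry point: build it from a roster of
spike trains plus a sleep-state epoch set, call :meth:`StateSynchrony.fit`,
and get a :class:`StateSynchronyResults` carrying the pair x state DCE
table, the stacked normalized CCGs, and the population summaries
(trough/peak proportions, state-specificity crosstabs, Tukey-corrected
|DCE| comparisons, spike/duration-matched downsampling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ccg import CCGParams, pair_dce
from .core import EpochSet, SpikeTrain, all_pairs, pair_key

STATE_ORDER = ("NREM", "WAKE", "REM")

TABLE_COLUMNS = ["unit_a", "unit_b", "state", "dce", "p", "significant"]


def _trains_by_id(trains) -> dict:
    return {t.unit_id: t for t in trains}


def state_dce_table(trains, states: EpochSet, params: CCGParams | None = None,
                    pairs=None, keep_nccg: bool = False,
                    recording_id: str | None = None):
    """DCE for every unordered unit pair in every present sleep state.

    Returns a tidy DataFrame (one row per pair x state) and, when
    ``keep_nccg``, a dict ``{(pair, state): NormalizedCCG}``.
    """
    params = params or CCGParams()
    if len(trains) < 2:
        raise ValueError("need at least two spike trains")
    by_id = _trains_by_id(trains)
    if pairs is None:
        pairs = all_pairs([t.unit_id for t in trains])
    present = [s for s in STATE_ORDER if s in states.label_set()
               and states.total_duration(s) > 0]
    rows = []
    nccgs = {}
    for state in present:
        for ua, ub in pairs:
            ka, kb = pair_key(ua, ub)
            nccg, res = pair_dce(by_id[ka], by_id[kb], states, state, params)
            rows.append((ka, kb, state, res.dce, res.p_value, res.significant))
            if keep_nccg:
                nccgs[((ka, kb), state)] = nccg
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    table.attrs["recording_id"] = recording_id
    if keep_nccg:
        return table, nccgs
    return table


def proportion_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per state: percentage of pairs with a significant trough (dce < 0)
    or peak (dce > 0); non-significant DCE counts as zero."""
    if table.empty:
        raise ValueError("empty DCE table")
    out = []
    for state, grp in table.groupby("state", sort=False):
        n = len(grp)
        sig = grp[grp["significant"]]
        out.append({
            "state": state,
            "n_pairs": n,
            "trough_pct": 100.0 * (sig["dce"] < 0).sum() / n,
            "peak_pct": 100.0 * (sig["dce"] > 0).sum() / n,
        })
    df = pd.DataFrame(out).set_index("state")
    return df.reindex([s for s in STATE_ORDER if s in df.index])


def state_specificity_crosstab(table: pd.DataFrame) -> pd.DataFrame:
    """For each ordered state pair (X, Y): percentage of all pairs with a
    significant negative DCE in X and a non-significant ("zero") DCE in Y."""
    states = [s for s in STATE_ORDER if s in set(table["state"])]
    if len(states) < 2:
        raise ValueError("crosstab needs at least two states")
    wide = table.pivot(index=["unit_a", "unit_b"], columns="state",
                       values=["dce", "significant"])
    n = len(wide)
    out = pd.DataFrame(np.nan, index=states, columns=states)
    for x in states:
        neg_x = wide[("significant", x)] & (wide[("dce", x)] < 0)
        for y in states:
            if x == y:
                continue
            zero_y = ~wide[("significant", y)].astype(bool)
            out.loc[x, y] = 100.0 * (neg_x & zero_y).sum() / n
    out.index.name = "negative_in"
    out.columns.name = "zero_in"
    return out


@dataclass
class AbsDCEComparison:
    """One-way comparison of |DCE| across states with Tukey-corrected
    pairwise p-values."""

    n_pairs: int
    group_means: pd.Series
    anova_p: float
    pairwise: pd.DataFrame  # columns: state_a, state_b, p

    def __repr__(self):
        return (f"AbsDCEComparison(n_pairs={self.n_pairs}, "
                f"anova_p={self.anova_p:.3g})")


def compare_abs_dce(table: pd.DataFrame, selection: str = "all") -> AbsDCEComparison:
    """Compare mean |DCE| across states for pairs significant in all states
    (``selection='all'``) or in one named state."""
    states = [s for s in STATE_ORDER if s in set(table["state"])]
    if len(states) < 2:
        raise ValueError("need at least two states to compare")
    wide = table.pivot(index=["unit_a", "unit_b"], columns="state",
                       values=["dce", "significant"])
    if selection == "all":
        mask = np.logical_and.reduce(
            [wide[("significant", s)].astype(bool) for s in states])
    elif selection in states:
        mask = wide[("significant", selection)].astype(bool)
    else:
        raise ValueError(f"unknown selection {selection!r}")
    sel = wide[mask]
    if sel.empty:
        return AbsDCEComparison(0, pd.Series(dtype=float), float("nan"),
                                pd.DataFrame(columns=["state_a", "state_b", "p"]))
    groups = [np.abs(sel[("dce", s)].to_numpy(dtype=float)) for s in states]
    means = pd.Series([g.mean() for g in groups], index=states, name="mean_abs_dce")
    if len(sel) < 2 or all(np.ptp(g) == 0 for g in groups):
        anova_p = 1.0
        pw = [(states[i], states[j], 1.0)
              for i in range(len(states)) for j in range(i + 1, len(states))]
    else:
        anova_p = float(stats.f_oneway(*groups).pvalue)
        tk = stats.tukey_hsd(*groups)
        pw = [(states[i], states[j], float(tk.pvalue[i, j]))
              for i in range(len(states)) for j in range(i + 1, len(states))]
    return AbsDCEComparison(int(len(sel)), means, anova_p,
                            pd.DataFrame(pw, columns=["state_a", "state_b", "p"]))


def _select_epochs_to_duration(starts, ends, target: float,
                               rng: np.random.Generator):
    """Whole epochs in random order until cumulative duration first reaches
    ``target`` (slight overshoot allowed)."""
    order = rng.permutation(starts.size)
    dur = 0.0
    chosen = []
    for i in order:
        chosen.append(i)
        dur += ends[i] - starts[i]
        if dur >= target:
            break
    idx = np.sort(np.asarray(chosen))
    return starts[idx], ends[idx]


def downsample_matched_dce(trains, states: EpochSet,
                           params: CCGParams | None = None, reps: int = 3,
                           seed=None, pairs=None) -> pd.DataFrame:
    """Duration- and spike-matched per-state DCE.

    Per repetition: (1) whole epochs of the longer states are sampled at
    random without replacement until their total duration first reaches that
    of the shortest state (normally REM); (2) in-epoch spikes of every state
    are randomly thinned to the minimum per-state count; (3) DCE is computed
    per pair per state.  Reported dce is the mean over repetitions and
    significance a majority vote.
    """
    params = params or CCGParams()
    rng = np.random.default_rng(seed)
    by_id = _trains_by_id(trains)
    unit_ids = [t.unit_id for t in trains]
    if pairs is None:
        pairs = all_pairs(unit_ids)
    present = [s for s in STATE_ORDER if s in states.label_set()
               and states.total_duration(s) > 0]
    if not present:
        raise ValueError("no sleep states present")
    ref_state = min(present, key=states.total_duration)
    ref_dur = states.total_duration(ref_state)
    if ref_dur <= 0:
        raise ValueError("reference state has zero duration")

    per_rep = []
    for _ in range(reps):
        sel = {}
        for s in present:
            st, en = states.select(s)
            if s == ref_state:
                sel[s] = (st, en)
            else:
                sel[s] = _select_epochs_to_duration(st, en, ref_dur, rng)
        # pooled in-epoch spikes per state, thinned to the common minimum
        state_spikes = {}
        for s in present:
            st, en = sel[s]
            units, times = [], []
            for uid in unit_ids:
                t = by_id[uid].restrict(st, en)
                units.append(np.full(t.size, uid, dtype=object))
                times.append(t)
            state_spikes[s] = (np.concatenate(units), np.concatenate(times))
        n_min = min(t.size for _, t in state_spikes.values())
        rows = []
        for s in present:
            units, times = state_spikes[s]
            keep = rng.choice(times.size, size=n_min, replace=False)
            units, times = units[keep], times[keep]
            st, en = sel[s]
            ep = EpochSet(st, en, np.full(st.size, s, dtype=object))
            sub = {}
            for uid in unit_ids:
                tt = np.sort(times[units == uid])
                sub[uid] = SpikeTrain(uid, tt, by_id[uid].t_start, by_id[uid].t_end)
            for ua, ub in pairs:
                ka, kb = pair_key(ua, ub)
                _, res = pair_dce(sub[ka], sub[kb], ep, s, params)
                rows.append((ka, kb, s, res.dce, res.p_value, res.significant))
        per_rep.append(pd.DataFrame(rows, columns=TABLE_COLUMNS))

    combined = pd.concat(per_rep)
    agg = combined.groupby(["unit_a", "unit_b", "state"], sort=False).agg(
        dce=("dce", "mean"), p=("p", "median"),
        significant=("significant", lambda s: s.sum() * 2 > len(s)),
    ).reset_index()
    return agg


def stacked_matrix(nccgs: dict, table: pd.DataFrame, state: str,
                   sort_state: str = "NREM", significant_only: bool = True):
    """Stacked normalized CCGs of ``state``, rows sorted by the DCE of
    ``sort_state`` (the paper-style stacked-CCG display, as a matrix).

    Returns (matrix, ordered list of pairs, lag_centers).
    """
    sorter = table[table["state"] == sort_state].copy()
    if significant_only:
        sorter = sorter[sorter["significant"]]
    sorter = sorter.sort_values("dce")
    pairs = [(r.unit_a, r.unit_b) for r in sorter.itertuples()]
    rows = [nccgs[(p, state)].values for p in pairs if (p, state) in nccgs]
    pairs = [p for p in pairs if (p, state) in nccgs]
    if not rows:
        return np.empty((0, 0)), [], np.empty(0)
    lag = nccgs[(pairs[0], state)].lag_centers
    return np.vstack(rows), pairs, lag


class StateSynchrony:
    """Population model of state-resolved pairwise spike synchrony.

    Parameters
    ----------
    trains : sequence of SpikeTrain
    states : EpochSet with WAKE/NREM/REM labels
    params : CCGParams, optional
    pairs : optional explicit list of unordered unit-id pairs; defaults to
        all pairs of the roster.
    """

    def __init__(self, trains, states: EpochSet, params: CCGParams | None = None,
                 pairs=None, recording_id: str | None = None):
        self.trains = list(trains)
        self.states = states
        self.params = params or CCGParams()
        self.pairs = pairs
        self.recording_id = recording_id

    @classmethod
    def from_dataframe(cls, spikes: pd.DataFrame, epochs: pd.DataFrame, **kw):
        """Build from tidy tables: spikes(unit_id, time_s),
        epochs(start_s, end_s, label)."""
        t_end = float(spikes["time_s"].max()) if len(spikes) else 0.0
        trains = [SpikeTrain(uid, np.sort(g["time_s"].to_numpy()), 0.0, t_end)
                  for uid, g in spikes.groupby("unit_id", sort=True)]
        states = EpochSet(epochs["start_s"].to_numpy(),
                          epochs["end_s"].to_numpy(),
                          epochs["label"].to_numpy(dtype=object))
        return cls(trains, states, **kw)

    def fit(self, keep_nccg: bool = True) -> "StateSynchronyResults":
        table, nccgs = state_dce_table(
            self.trains, self.states, self.params, self.pairs,
            keep_nccg=True, recording_id=self.recording_id)
        if not keep_nccg:
            nccgs = {}
        return StateSynchronyResults(self, table, nccgs)


class StateSynchronyResults:
    """Fitted pair x state DCE table plus population summaries."""

    def __init__(self, model: StateSynchrony, table: pd.DataFrame, nccgs: dict):
        self.model = model
        self.table = table
        self.nccgs = nccgs

    def proportion_summary(self) -> pd.DataFrame:
        return proportion_summary(self.table)

    def specificity_crosstab(self) -> pd.DataFrame:
        return state_specificity_crosstab(self.table)

    def compare_abs_dce(self, selection: str = "all") -> AbsDCEComparison:
        return compare_abs_dce(self.table, selection)

    def downsampled(self, reps: int = 3, seed=None) -> pd.DataFrame:
        return downsample_matched_dce(self.model.trains, self.model.states,
                                      self.model.params, reps, seed,
                                      self.model.pairs)

    def stacked(self, state: str, sort_state: str = "NREM",
                significant_only: bool = True):
        return stacked_matrix(self.nccgs, self.table, state, sort_state,
                              significant_only)

    def summary(self) -> str:
        lines = ["State-resolved pairwise synchrony (DCE) summary",
                 "=" * 48]
        if self.model.recording_id:
            lines.append(f"recording: {self.model.recording_id}")
        n_pairs = len(self.table[["unit_a", "unit_b"]].drop_duplicates())
        lines.append(f"pairs: {n_pairs}   states: "
                     + ", ".join(sorted(set(self.table['state'])))
                     + f"   alpha: {self.model.params.alpha:g}")
        lines.append("")
        lines.append(self.proportion_summary().round(2).to_string())
        return "\n".join(lines)
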