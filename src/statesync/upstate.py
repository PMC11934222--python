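"""UP-state-specific analyses.

Covers: UP/DOWN detection from population rate, UP-state-only CCG/DCE
(2 s lag span, edges at 1-2 s), the "UPnext" scrambling control (one unit's
per-UP spike pattern shifted to the previous UP state), per-unit UP-phase
spike profiles, resimulation of a pair from its averaged profiles with a
z-test null, and within-UP first/mean spike-time difference metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .ccg import CCGParams, UP_ONLY, pair_dce
from .core import EpochSet, SpikeTrain


def detect_up_down(trains, nrem_epochs: EpochSet, bin_width: float = 0.01,
                   smooth_bins: int = 3, rate_fraction: float = 0.1,
                   min_down: float = 0.05, min_up: float = 0.1) -> EpochSet:
    """Detect UP/DOWN states from the smoothed population rate.

    DOWN = maximal runs of 10 ms bins below ``rate_fraction`` of the mean
    nonREM population rate lasting >= ``min_down``; UP = the complementary
    intervals of duration >= ``min_up``.  Supply curated epochs instead to
    skip detection entirely.
    """
    starts, ends = nrem_epochs.select("NREM")
    if starts.size == 0:
        raise ValueError("no nonREM epochs")
    ivs = []
    all_times = [t.times for t in trains]
    for s, e in zip(starts, ends):
        nbins = max(1, int(np.ceil((e - s) / bin_width)))
        counts = np.zeros(nbins)
        for times in all_times:
            tt = times[(times >= s) & (times < e)]
            if tt.size:
                counts += np.bincount(((tt - s) / bin_width).astype(int),
                                      minlength=nbins)[:nbins]
        rate = ndimage.uniform_filter1d(counts, smooth_bins) / bin_width
        thresh = rate_fraction * rate.mean()
        low = rate < thresh
        # maximal low runs -> DOWN candidates
        edges = np.diff(np.concatenate([[0], low.view(np.int8), [0]]))
        run_starts = np.flatnonzero(edges == 1)
        run_ends = np.flatnonzero(edges == -1)
        downs = []
        for r0, r1 in zip(run_starts, run_ends):
            t0, t1 = s + r0 * bin_width, min(s + r1 * bin_width, e)
            if t1 - t0 >= min_down:
                downs.append((t0, t1))
        prev = s
        for t0, t1 in downs:
            if t0 - prev >= min_up:
                ivs.append((prev, t0, "UP"))
            ivs.append((t0, t1, "DOWN"))
            prev = t1
        if e - prev >= min_up:
            ivs.append((prev, e, "UP"))
    return EpochSet.from_tuples(ivs)


def up_only_dce(a: SpikeTrain, b: SpikeTrain, up_epochs: EpochSet,
                params: CCGParams | None = None, trim_to=None):
    """DCE from CCGs summed over UP states only (UP_ONLY variant: +-2 s
    lags, edge windows at 1-2 s).

    ``trim_to`` (sequence of per-UP durations) truncates each UP state
    before counting, used to duration-match the scrambled control.
    """
    params = (params or CCGParams()).for_up_only()
    starts, ends = up_epochs.select("UP")
    if starts.size < 1:
        raise ValueError("no UP epochs")
    if trim_to is not None:
        trim_to = np.asarray(trim_to, float)
        if trim_to.size != starts.size:
            raise ValueError("trim_to length must match the number of UPs")
        ends = np.minimum(ends, starts + trim_to)
        keep = ends > starts
        starts, ends = starts[keep], ends[keep]
    ep = EpochSet(starts, ends, np.full(starts.size, "UP", dtype=object))
    return pair_dce(a, b, ep, "UP", params, variant=UP_ONLY)


def scramble_up_next(a: SpikeTrain, up_epochs: EpochSet):
    """UPnext control: shift unit ``a``'s per-UP spike pattern to the
    previous UP state.

    For each UP state N >= 2, a's spikes from UP N (as offsets from that
    UP's onset) are re-anchored at UP N-1's onset; the receiving UP is
    trimmed to min(dur(N-1), dur(N)) and overhanging spikes discarded.  The
    unshifted partner is analyzed on the same trimmed epochs, which also
    truncate its spikes.  Returns (shifted SpikeTrain, trimmed EpochSet);
    the last original UP state no longer receives any pattern and is
    dropped.
    """
    starts, ends = up_epochs.select("UP")
    if starts.size < 2:
        raise ValueError("UPnext scrambling needs at least 2 UP states")
    durs = ends - starts
    trimmed = np.minimum(durs[:-1], durs[1:])
    new_times = []
    for k in range(1, starts.size):
        t = a.times[(a.times >= starts[k]) & (a.times < ends[k])]
        off = t - starts[k]
        off = off[off < trimmed[k - 1]]
        new_times.append(starts[k - 1] + off)
    times = np.sort(np.concatenate(new_times)) if new_times else np.empty(0)
    shifted = SpikeTrain(a.unit_id, times, a.t_start, a.t_end)
    ep = EpochSet(starts[:-1], starts[:-1] + trimmed,
                  np.full(starts.size - 1, "UP", dtype=object))
    return shifted, ep


def scrambled_up_dce(a: SpikeTrain, b: SpikeTrain, up_epochs: EpochSet,
                     params: CCGParams | None = None):
    """(original-but-trimmed DCE, UPnext-scrambled DCE) on matched UP
    durations."""
    a_sh, trimmed = scramble_up_next(a, up_epochs)
    _, orig = up_only_dce(a, b, trimmed, params)
    _, scram = up_only_dce(a_sh, b, trimmed, params)
    return orig, scram


@dataclass
class UpProfile:
    """Per-unit spike probability over 50 normalized UP-phase bins."""

    unit_id: object
    bin_probs: np.ndarray
    mean_rate_up: float

    def __post_init__(self):
        self.bin_probs = np.asarray(self.bin_probs, float)
        if self.bin_probs.size != 50:
            raise ValueError("profile must have exactly 50 phase bins")
        if abs(self.bin_probs.sum() - 1.0) > 1e-9:
            raise ValueError("bin probabilities must sum to 1")


def up_spike_profile(train: SpikeTrain, up_epochs: EpochSet,
                     n_bins: int = 50) -> UpProfile:
    """Average per-UP spike-phase probability distribution.

    Each UP state's spikes are binned over normalized phase (0 = onset,
    1 = offset) and converted to a probability distribution; distributions
    are averaged over UP states (UPs without spikes are skipped).
    """
    starts, ends = up_epochs.select("UP")
    if starts.size == 0:
        raise ValueError("no UP epochs")
    acc = np.zeros(n_bins)
    n_used = 0
    total_spikes = 0
    for s, e in zip(starts, ends):
        t = train.times[(train.times >= s) & (train.times < e)]
        if t.size == 0:
            continue
        phase = np.clip((t - s) / (e - s), 0, 1 - 1e-12)
        h = np.bincount((phase * n_bins).astype(int), minlength=n_bins)
        acc += h / h.sum()
        n_used += 1
        total_spikes += t.size
    if n_used == 0:
        raise ValueError(f"unit {train.unit_id}: no UP-state spikes")
    probs = acc / n_used
    probs = probs / probs.sum()
    rate = total_spikes / float(np.sum(ends - starts))
    return UpProfile(train.unit_id, probs, rate)


def simulate_profile_pair(prof_a: UpProfile, prof_b: UpProfile,
                          updown_durations, seed=None, t_start: float = 0.0):
    """Simulate a pair from averaged UP-phase profiles.

    ``updown_durations``: sequence of (label, duration) alternating UP/DOWN.
    Within each UP of duration d the unit fires an inhomogeneous Poisson
    process with phase-bin rate ``mean_rate_up * 50 * bin_probs`` (so the
    UP firing rate is preserved); DOWN states are silent; the two trains
    are drawn independently.  Returns (train_a, train_b, EpochSet).
    """
    rng = np.random.default_rng(seed)
    t = t_start
    ivs = []
    for lab, d in updown_durations:
        ivs.append((t, t + d, lab))
        t += d
    ep = EpochSet.from_tuples(ivs)
    starts, ends = ep.select("UP")
    durs = ends - starts
    trains = []
    for prof in (prof_a, prof_b):
        n = rng.poisson(prof.mean_rate_up * durs)
        tot = int(n.sum())
        bins = rng.choice(50, size=tot, p=prof.bin_probs)
        phase = (bins + rng.random(tot)) / 50.0
        tt = np.sort(np.repeat(starts, n) + phase * np.repeat(durs, n))
        trains.append(SpikeTrain(prof.unit_id, tt, t_start, t))
    return trains[0], trains[1], ep


def dce_null_from_simulation(prof_a: UpProfile, prof_b: UpProfile,
                             updown_durations, observed_dce: float,
                             n_sims: int = 100, seed=None,
                             params: CCGParams | None = None):
    """Null DCE distribution from profile-based resimulation.

    Simulates the pair ``n_sims`` times, computes the UP-only DCE of each
    simulation, and z-tests the observed DCE against that null.
    Returns (null_mean, null_sd, z, p, null_values).
    """
    if n_sims < 30:
        raise ValueError("need at least 30 simulations for a stable null")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_sims)
    for i in range(n_sims):
        a, b, ep = simulate_profile_pair(prof_a, prof_b, updown_durations,
                                         seed=rng.integers(2 ** 31))
        _, res = up_only_dce(a, b, ep, params)
        vals[i] = res.dce
    mu, sd = float(vals.mean()), float(vals.std(ddof=1))
    if sd <= 0:
        raise ValueError("degenerate null distribution (sd = 0)")
    z = (observed_dce - mu) / sd
    p = float(2.0 * stats.norm.sf(abs(z)))
    return mu, sd, float(z), p, vals


@dataclass
class SpikeTimingMetrics:
    """Mean and SD across UP states of per-UP first/mean spike-time
    differences (seconds; a minus b), over UPs where both units fire."""

    pair: tuple
    mean_diff_first: float
    sd_diff_first: float
    mean_diff_mean: float
    sd_diff_mean: float
    n_up_states_used: int
    flagged: bool = False
    diffs_first: np.ndarray | None = None
    diffs_mean: np.ndarray | None = None


def up_timing_metrics(a: SpikeTrain, b: SpikeTrain, up_epochs: EpochSet,
                      min_ups: int = 10) -> SpikeTimingMetrics:
    """Per-UP spike-timing differences between a pair.

    For every UP state where both units fire at least once:
    diff_first = first(a) - first(b), diff_mean = mean(a) - mean(b),
    both relative to the UP onset; summarized by mean and SD across UPs.
    """
    starts, ends = up_epochs.select("UP")
    d_first, d_mean = [], []
    for s, e in zip(starts, ends):
        ta = a.times[(a.times >= s) & (a.times < e)]
        tb = b.times[(b.times >= s) & (b.times < e)]
        if ta.size == 0 or tb.size == 0:
            continue
        d_first.append(ta[0] - tb[0])
        d_mean.append(ta.mean() - tb.mean())
    d_first = np.asarray(d_first)
    d_mean = np.asarray(d_mean)
    n = d_first.size
    if n == 0:
        return SpikeTimingMetrics((a.unit_id, b.unit_id), np.nan, np.nan,
                                  np.nan, np.nan, 0, flagged=True)
    return SpikeTimingMetrics(
        (a.unit_id, b.unit_id),
        float(d_first.mean()), float(d_first.std(ddof=1)) if n > 1 else 0.0,
        float(d_mean.mean()), float(d_mean.std(ddof=1)) if n > 1 else 0.0,
        n, flagged=(n < min_ups), diffs_first=d_first, diffs_mean=d_mean)


METRIC_FIELDS = ("mean_diff_first", "sd_diff_first", "mean_diff_mean",
                 "sd_diff_mean")


def timing_metric_contrast(metrics, dce_table: pd.DataFrame,
                           state: str = "NREM", min_group: int = 5,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Compare timing metrics between trough and peak pairs.

    Pairs are grouped by the sign of their significant DCE in ``state``;
    each of the four metrics is compared across groups with a two-sample
    rank-sum test.  Also reports, per group, the fraction of pairs whose
    per-UP differences are significantly nonzero (one-sample t-test).
    """
    sig = dce_table[(dce_table["state"] == state) & dce_table["significant"]]
    sign = {(r.unit_a, r.unit_b): np.sign(r.dce) for r in sig.itertuples()}
    trough = [m for m in metrics if sign.get(m.pair) == -1 and not m.flagged]
    peak = [m for m in metrics if sign.get(m.pair) == 1 and not m.flagged]
    if len(trough) < min_group or len(peak) < min_group:
        raise ValueError(
            f"need >= {min_group} trough and peak pairs "
            f"(got {len(trough)}, {len(peak)})")

    def frac_nonzero(group, attr):
        arrs = [getattr(m, "diffs_first" if "first" in attr else "diffs_mean")
                for m in group]
        ps = [stats.ttest_1samp(x, 0.0).pvalue for x in arrs if x.size > 1]
        return float(np.mean(np.asarray(ps) < alpha)) if ps else np.nan

    rows = []
    for f in METRIC_FIELDS:
        tv = np.array([getattr(m, f) for m in trough])
        pv = np.array([getattr(m, f) for m in peak])
        stat, p = stats.mannwhitneyu(tv, pv, alternative="two-sided")
        row = {"metric": f, "trough_mean": tv.mean(), "peak_mean": pv.mean(),
               "p": float(p), "n_trough": len(tv), "n_peak": len(pv)}
        if f.startswith("mean_"):
            row["frac_nonzero_trough"] = frac_nonzero(trough, f)
            row["frac_nonzero_peak"] = frac_nonzero(peak, f)
        rows.append(row)
    return pd.DataFrame(rows)
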