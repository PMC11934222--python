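"""LFP band power and its relation to pairwise anticorrelation strength.

Band power is estimated Welch-style (1 s sliding windows, half overlap) and
z-scored over time within a recording with |z| > 3 outliers removed, after
which three readouts relate it to the DCE:

* 3-h-windowed Spearman correlation between per-window nonREM |DCE| (or
  signed DCE) and mean normalized band power,
* per-nonREM-epoch band-power quartiles with a CCG/DCE per quartile,
* Pearson correlation between nonREM epoch duration and plateau band power
  (epochs > 200 s, first 120 s and last 50 s trimmed).

Plus a pair x 3-h-window DCE stability matrix compared against within-window
shuffles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .ccg import CCGParams, pair_dce
from .core import EpochSet, pair_key

#: example delta / gamma bands highlighted by the analysis
DELTA_BAND = (3.5, 4.3)
GAMMA_BAND = (49.0, 60.0)


def default_bands(n: int = 20, f_lo: float = 0.5, f_hi: float = 100.0):
    """Log-spaced band grid including the canonical delta and gamma bands."""
    edges = np.geomspace(f_lo, f_hi, n + 1)
    bands = [(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])]
    return bands + [DELTA_BAND, GAMMA_BAND]


@dataclass
class LFP:
    """Single-channel LFP trace: samples at a fixed rate from ``t_start``."""

    samples: np.ndarray
    rate: float
    t_start: float = 0.0

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.samples.size) / self.rate


@dataclass
class BandPower:
    """Band-limited power over time (optionally z-scored, outliers removed)."""

    band: tuple
    times: np.ndarray
    power: np.ndarray
    normalized: bool

    def mean_in(self, starts, ends) -> float:
        """Mean power of samples whose window centers fall in the intervals."""
        starts = np.atleast_1d(np.asarray(starts, float))
        ends = np.atleast_1d(np.asarray(ends, float))
        m = np.zeros(self.times.size, dtype=bool)
        for s, e in zip(starts, ends):
            m |= (self.times >= s) & (self.times < e)
        return float(self.power[m].mean()) if m.any() else float("nan")


def _znorm(power: np.ndarray, z_cut: float = 3.0):
    """Z-score over time; samples beyond |z| > 3 of the raw distribution
    are dropped and the retained set re-standardized.

    A single exclusion pass only: iterating the exclusion to a fixed point
    would cascade on bimodal band-power distributions (e.g. delta power,
    where the nonREM mode sits far above wake) and delete a whole mode.
    The transform is idempotent once the outlier set is stable."""
    mu, sd = power.mean(), power.std()
    if sd == 0:
        return np.zeros_like(power), np.ones(power.size, dtype=bool)
    keep = np.abs((power - mu) / sd) <= z_cut
    mu, sd = power[keep].mean(), power[keep].std()
    if sd == 0:
        sd = 1.0
    return (power - mu) / sd, keep


def band_power_timeseries(lfp: LFP, bands, window_s: float = 1.0,
                          epochs: EpochSet | None = None, label: str | None = None,
                          normalized: bool = True) -> list[BandPower]:
    """Welch-style sliding-window band power, one series per band.

    Windows of ``window_s`` with half overlap; per window the periodogram is
    integrated over each band.  With ``epochs``/``label`` the series is
    restricted to windows whose centers fall in the labeled epochs.
    """
    nper = int(round(window_s * lfp.rate))
    freqs, t, sxx = signal.spectrogram(lfp.samples, fs=lfp.rate, nperseg=nper,
                                       noverlap=nper // 2, scaling="density")
    t = t + lfp.t_start
    nyq = lfp.rate / 2.0
    out = []
    for f_lo, f_hi in bands:
        if f_lo >= f_hi:
            raise ValueError("band must satisfy f_lo < f_hi")
        if f_hi > nyq + 1e-9:
            raise ValueError(f"band {(f_lo, f_hi)} above Nyquist {nyq} Hz")
        sel = (freqs >= f_lo) & (freqs < f_hi)
        if not sel.any():  # band narrower than the frequency resolution
            sel = np.argmin(np.abs(freqs - 0.5 * (f_lo + f_hi)))
        power = sxx[sel].sum(axis=0) * (freqs[1] - freqs[0])
        power = np.atleast_1d(power)
        times = t.copy()
        if epochs is not None and label is not None:
            s, e = epochs.select(label)
            m = np.zeros(times.size, dtype=bool)
            for a, b in zip(s, e):
                m |= (times >= a) & (times < b)
            times, power = times[m], power[m]
        if normalized and power.size:
            z, keep = _znorm(power)
            times, power = times[keep], z[keep]
        out.append(BandPower((f_lo, f_hi), times, power, normalized))
    return out


def trough_pair_selection(table: pd.DataFrame, state: str = "NREM",
                          sign: int = -1) -> list[tuple]:
    """Pairs with a significant negative (or positive) whole-recording DCE."""
    t = table[(table["state"] == state) & table["significant"]]
    t = t[t["dce"] * sign > 0]
    return [(r.unit_a, r.unit_b) for r in t.itertuples()]


def _windows(t_start: float, t_end: float, window_s: float,
             min_last: float = 3600.0):
    """3-h windows anchored at recording start; final partial window kept
    if at least ``min_last`` long."""
    out = []
    t = t_start
    while t < t_end - 1e-9:
        e = min(t + window_s, t_end)
        if e - t >= min_last or e - t >= window_s - 1e-9:
            out.append((t, e))
        t += window_s
    return out


def windowed_dce(trains, states: EpochSet, pairs, window_s: float = 10800.0,
                 params: CCGParams | None = None, state: str = "NREM",
                 t_start: float | None = None, t_end: float | None = None
                 ) -> pd.DataFrame:
    """NREM-only DCE of each pair inside consecutive 3-h windows."""
    params = params or CCGParams()
    by_id = {t.unit_id: t for t in trains}
    if t_start is None:
        t_start = min(t.t_start for t in trains)
    if t_end is None:
        t_end = max(t.t_end for t in trains)
    rows = []
    for w0, w1 in _windows(t_start, t_end, window_s):
        win = states.intersect_window(w0, w1)
        if state not in win.label_set():
            continue
        for ua, ub in pairs:
            ka, kb = pair_key(ua, ub)
            try:
                _, res = pair_dce(by_id[ka], by_id[kb], win, state, params)
            except ValueError:
                continue
            rows.append((ka, kb, w0, w1 - w0, res.dce, res.p_value,
                         res.significant))
    return pd.DataFrame(rows, columns=["unit_a", "unit_b", "window_start",
                                       "window_len", "dce", "p", "significant"])


def windowed_dce_power_correlation(trains, states: EpochSet, lfp: LFP, bands,
                                   pairs, window_s: float = 10800.0,
                                   params: CCGParams | None = None,
                                   signed: bool = False) -> pd.DataFrame:
    """Spearman R between per-window |DCE| (signed DCE with ``signed``) and
    the window's mean normalized nonREM band power, pooled over pairs and
    windows; one row per band.  Rows with fewer than 10 points are flagged.
    """
    wdce = windowed_dce(trains, states, pairs, window_s, params)
    bps = band_power_timeseries(lfp, bands, epochs=states, label="NREM",
                                normalized=True)
    rows = []
    for bp in bps:
        xs, ys = [], []
        for w0, grp in wdce.groupby("window_start"):
            wlen = grp["window_len"].iloc[0]
            p = bp.mean_in(w0, w0 + wlen)
            if np.isnan(p):
                continue
            vals = grp["dce"].to_numpy()
            if not signed:
                vals = np.abs(vals)
            xs.extend([p] * vals.size)
            ys.extend(vals.tolist())
        xs, ys = np.asarray(xs), np.asarray(ys)
        flagged = xs.size < 10 or np.ptp(xs) == 0
        if flagged:
            r, p = float("nan"), float("nan")
        else:
            r, p = stats.spearmanr(xs, ys)
        rows.append((bp.band[0], bp.band[1], float(r), float(p), xs.size,
                     flagged))
    return pd.DataFrame(rows, columns=["f_lo", "f_hi", "R", "p", "n_points",
                                       "flagged"])


def quartile_dce_power(trains, nrem_epochs: EpochSet, lfp: LFP, band, pairs,
                       params: CCGParams | None = None, label: str = "NREM"):
    """Rank nonREM epochs into four band-power quartiles and compute each
    pair's DCE from each quartile's epochs alone.

    Returns (per-quartile table, Pearson R, p) with R over pooled
    (quartile power, dce) points.
    """
    params = params or CCGParams()
    starts, ends = nrem_epochs.select(label)
    if starts.size < 8:
        raise ValueError("need at least 8 nonREM epochs for quartiles")
    bp = band_power_timeseries(lfp, [band], normalized=True)[0]
    ep_power = np.array([bp.mean_in(s, e) for s, e in zip(starts, ends)])
    ep_power = np.nan_to_num(ep_power, nan=np.nanmean(ep_power))
    order = np.argsort(ep_power, kind="stable")  # stable tie-break
    qs = np.array_split(order, 4)
    by_id = {t.unit_id: t for t in trains}
    rows = []
    for qi, idx in enumerate(qs):
        if idx.size == 0:
            raise ValueError("empty power quartile")
        ep = EpochSet(starts[idx], ends[idx],
                      np.full(idx.size, label, dtype=object))
        qpow = float(ep_power[idx].mean())
        for ua, ub in pairs:
            ka, kb = pair_key(ua, ub)
            _, res = pair_dce(by_id[ka], by_id[kb], ep, label, params)
            rows.append((qi + 1, qpow, ka, kb, res.dce, res.significant))
    df = pd.DataFrame(rows, columns=["quartile", "mean_power", "unit_a",
                                     "unit_b", "dce", "significant"])
    if df["mean_power"].nunique() < 2:
        return df, float("nan"), float("nan")
    r, p = stats.pearsonr(df["mean_power"], df["dce"])
    return df, float(r), float(p)


def epoch_duration_power_correlation(nrem_epochs: EpochSet, lfp: LFP, bands,
                                     min_duration: float = 200.0,
                                     trim_start: float = 120.0,
                                     trim_end: float = 50.0,
                                     label: str = "NREM") -> pd.DataFrame:
    """Pearson R between nonREM epoch duration and plateau band power.

    Only epochs longer than ``min_duration`` qualify; the first
    ``trim_start`` s and last ``trim_end`` s are excluded from the power
    average so the duration-independent ramps do not bias short epochs.
    """
    starts, ends = nrem_epochs.select(label)
    dur = ends - starts
    qual = dur > min_duration
    qual &= dur > trim_start + trim_end  # trimming guard
    n_excluded = int((~qual).sum())
    if qual.sum() < 10:
        raise ValueError("fewer than 10 qualifying nonREM epochs")
    s_q, e_q, d_q = starts[qual], ends[qual], dur[qual]
    bps = band_power_timeseries(lfp, bands, normalized=True)
    rows = []
    for bp in bps:
        pw = np.array([bp.mean_in(s + trim_start, e - trim_end)
                       for s, e in zip(s_q, e_q)])
        ok = ~np.isnan(pw)
        if ok.sum() < 3 or np.ptp(d_q[ok]) == 0:
            r, p, flagged = float("nan"), float("nan"), True
        else:
            r, p = stats.pearsonr(d_q[ok], pw[ok])
            flagged = False
        rows.append((bp.band[0], bp.band[1], float(r), float(p),
                     int(ok.sum()), n_excluded, flagged))
    return pd.DataFrame(rows, columns=["f_lo", "f_hi", "R", "p", "n_epochs",
                                       "n_excluded", "flagged"])


@dataclass
class StabilityReport:
    """Pair x window DCE matrix and its temporal-stability test."""

    matrix: pd.DataFrame  # index pair, columns window start
    mean_sd: float
    shuffled_mean: float
    shuffled_sd: float
    z: float
    p: float


def dce_stability_matrix(trains, states: EpochSet, table: pd.DataFrame,
                         window_s: float = 10800.0, n_units: int = 20,
                         params: CCGParams | None = None, n_shuffles: int = 200,
                         seed=None) -> StabilityReport:
    """Temporal stability of pairwise DCE.

    The ``n_units`` units participating in the most significant-negative
    nonREM pairs are selected; their trough pairs' DCE is computed per 3-h
    window; the mean over pairs of the across-window SD is compared (z-test)
    against the distribution obtained by shuffling values across pairs
    within each window.
    """
    rng = np.random.default_rng(seed)
    neg = table[(table["state"] == "NREM") & table["significant"]
                & (table["dce"] < 0)]
    if neg.empty:
        raise ValueError("no significant-negative NREM pairs")
    # most anticorrelated pairs first, until n_units units are involved
    counts = pd.concat([neg["unit_a"], neg["unit_b"]]).value_counts()
    neg = neg.assign(_deg=[counts[r.unit_a] + counts[r.unit_b]
                           for r in neg.itertuples()])
    neg = neg.sort_values(["_deg", "dce"], ascending=[False, True])
    units: set = set()
    sel_pairs = []
    for r in neg.itertuples():
        if len(units) >= n_units and not {r.unit_a, r.unit_b} <= units:
            continue
        sel_pairs.append((r.unit_a, r.unit_b))
        units |= {r.unit_a, r.unit_b}
    wdce = windowed_dce(trains, states, sel_pairs, window_s, params)
    mat = wdce.pivot_table(index=["unit_a", "unit_b"], columns="window_start",
                           values="dce")
    if mat.shape[1] < 2:
        raise ValueError("stability analysis needs at least 2 windows")
    m = mat.to_numpy()
    real = float(np.nanstd(m, axis=1).mean())
    sh_means = np.empty(n_shuffles)
    for i in range(n_shuffles):
        shm = np.column_stack([rng.permutation(m[:, j])
                               for j in range(m.shape[1])])
        sh_means[i] = np.nanstd(shm, axis=1).mean()
    mu, sd = sh_means.mean(), sh_means.std()
    z = (real - mu) / sd if sd > 0 else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    return StabilityReport(mat, real, float(mu), float(sd), float(z), p)
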