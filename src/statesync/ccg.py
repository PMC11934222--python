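"""Cross-correlograms, baseline normalization, and the DCE statistic.

The pipeline implemented here quantifies pairwise spike timing at the
hundreds-of-milliseconds scale:

1. A raw CCG is the histogram of lags ``t_b - t_a`` between every pair of
   spikes of two units that fall inside the *same* labeled epoch; per-epoch
   histograms are summed over all epochs of the requested label.
2. The raw CCG is divided by a slow baseline that carries only the coarse
   (rate-covariation) timing content: either the raw CCG convolved with a
   1 s triangular window, or the CCG of locally jittered spike trains
   (0.5 s fixed partition windows).  The two baselines are equivalent in
   expectation; convolution is far cheaper.
3. The normalized CCG is the natural log of that ratio (with a pseudocount),
   so a structureless pair sits at 0 everywhere, peaks are positive and
   troughs negative on a comparable scale.
4. DCE ("difference between center and edges") = mean normalized amplitude
   in the central 250 ms window minus the mean over the outer edge windows,
   with significance from a two-sample Welch t-test over bin values at
   alpha = 1e-4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal, stats

from .core import EpochSet, SpikeTrain

STANDARD = "STANDARD"
UP_ONLY = "UP_ONLY"

ALPHA = 1e-4


@dataclass
class CCGParams:
    """Knobs of the CCG/DCE computation.

    bin_width 5 ms keeps the 250 ms center and 125 ms edge windows aligned
    with whole bins; max_lag 1 s (2 s for UP-only) spans the sub-500 ms
    content that survives normalization.
    """

    bin_width: float = 0.005
    max_lag: float = 1.0
    smooth_window: float = 1.0
    pseudocount: float = 1.0
    alpha: float = ALPHA
    baseline: str = "triangular"  # or "jitter"
    jitter_window: float = 0.5
    jitter_reps: int = 3

    def for_up_only(self) -> "CCGParams":
        return replace(self, max_lag=2.0)


@dataclass
class CCG:
    """Lag-binned spike coincidence counts summed over epochs."""

    pair: tuple
    lag_centers: np.ndarray
    counts: np.ndarray
    bin_width: float
    max_lag: float
    n_epochs: int
    empty: bool = False

    def __post_init__(self):
        if self.lag_centers.size != self.counts.size:
            raise ValueError("lag grid and counts length mismatch")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class NormalizedCCG:
    """Log-ratio normalized CCG (dimensionless; 0 = no fine structure)."""

    pair: tuple
    lag_centers: np.ndarray
    values: np.ndarray
    variant: str = STANDARD
    log_base: str = "e"

    @property
    def max_lag(self) -> float:
        return float(self.lag_centers[-1])


@dataclass
class DCEResult:
    """Center-minus-edge statistic of a normalized CCG.

    ``significant`` means the Welch t-test between center-window and
    edge-window bin values rejects at alpha = 1e-4; population summaries
    treat non-significant DCE as zero (``effective_dce``).
    """

    pair: tuple
    state_or_variant: str
    dce: float
    p_value: float
    significant: bool
    center_window: float = 0.25
    edge_window: float = 0.125
    n_center: int = 0
    n_edge: int = 0

    @property
    def effective_dce(self) -> float:
        return self.dce if self.significant else 0.0


def _lag_grid(bin_width: float, max_lag: float) -> np.ndarray:
    half = int(round(max_lag / bin_width))
    if abs(half * bin_width - max_lag) > 1e-9:
        raise ValueError("max_lag must be a positive integer multiple of bin_width")
    if half < 1:
        raise ValueError("max_lag must be at least one bin wide")
    return np.arange(-half, half + 1) * bin_width


def _concatenate_epochs(times: np.ndarray, starts: np.ndarray, ends: np.ndarray,
                        gap: float) -> np.ndarray:
    """Remap spikes of consecutive epochs onto a common axis with dead gaps.

    Epoch k is shifted so epochs are separated by more than ``gap``; lags
    between spikes of different epochs then never enter a +-gap histogram,
    which makes one global pass equivalent to per-epoch CCGs.
    """
    offsets = np.concatenate([[0.0], np.cumsum(ends[:-1] - starts[:-1] + 2.0 * gap)])
    lo = np.searchsorted(times, starts, side="left")
    hi = np.searchsorted(times, ends, side="left")
    return np.concatenate(
        [times[a:b] - s + off for a, b, s, off in zip(lo, hi, starts, offsets)]
    )


def compute_ccg(a: SpikeTrain, b: SpikeTrain, epochs: EpochSet, label: str,
                bin_width: float = 0.005, max_lag: float = 1.0) -> CCG:
    """CCG of lags ``t_b - t_a`` restricted to same-epoch spike pairs.

    Per-epoch histograms are summed over every epoch carrying ``label``.
    """
    starts, ends = epochs.select(label)
    if starts.size == 0:
        raise ValueError(f"no epochs labeled {label!r}")
    grid = _lag_grid(bin_width, max_lag)
    half = (grid.size - 1) // 2
    gap = max_lag + bin_width
    ta = _concatenate_epochs(a.times, starts, ends, gap)
    tb = _concatenate_epochs(b.times, starts, ends, gap)
    if ta.size == 0 or tb.size == 0:
        warnings.warn(
            f"pair {(a.unit_id, b.unit_id)}: no spikes in any {label!r} epoch",
            stacklevel=2,
        )
        return CCG((a.unit_id, b.unit_id), grid, np.zeros(grid.size), bin_width,
                   max_lag, int(starts.size), empty=True)
    lim = max_lag + bin_width / 2.0
    lo = np.searchsorted(tb, ta - lim, side="left")
    hi = np.searchsorted(tb, ta + lim, side="right")
    npairs = hi - lo
    keep = npairs > 0
    lo, npairs = lo[keep], npairs[keep]
    total = int(npairs.sum())
    counts = np.zeros(grid.size)
    if total:
        # gather all in-range b-spikes for each a-spike in one flat pass
        flat = np.repeat(lo + npairs - np.cumsum(npairs), npairs) + np.arange(total)
        lags = tb[flat] - np.repeat(ta[keep], npairs)
        idx = np.round(lags / bin_width).astype(np.int64) + half
        np.clip(idx, 0, grid.size - 1, out=idx)
        counts = np.bincount(idx, minlength=grid.size).astype(float)
    return CCG((a.unit_id, b.unit_id), grid, counts, bin_width, max_lag,
               int(starts.size), empty=(total == 0))


def smooth_triangular(ccg: CCG, window: float = 1.0) -> CCG:
    """Convolve the CCG with a unit-area triangular kernel of total width
    ``window`` (rounded to an odd bin count); boundary bins renormalize the
    kernel over the in-range support so a flat CCG stays exactly flat."""
    if window < 2.0 * ccg.bin_width:
        raise ValueError("smoothing window must span at least two bins")
    n = int(round(window / ccg.bin_width))
    if n % 2 == 0:
        n += 1
    kernel = signal.windows.triang(n)
    kernel /= kernel.sum()
    num = np.convolve(ccg.counts, kernel, mode="same")
    den = np.convolve(np.ones_like(ccg.counts), kernel, mode="same")
    return replace(ccg, counts=num / den)


def jitter_spike_train(train: SpikeTrain, epochs: EpochSet, label: str,
                       window: float, rng: np.random.Generator) -> SpikeTrain:
    """Re-draw each in-epoch spike uniformly within its fixed ``window``-s
    partition (partitions anchored at the epoch start; the trailing partial
    partition is truncated at the epoch end)."""
    starts, ends = epochs.select(label)
    pieces = []
    for s, e in zip(starts, ends):
        t = train.times[(train.times >= s) & (train.times < e)]
        if t.size == 0:
            continue
        k = np.floor((t - s) / window)
        w_lo = s + k * window
        w_hi = np.minimum(w_lo + window, e)
        pieces.append(w_lo + rng.random(t.size) * (w_hi - w_lo))
    # out-of-epoch spikes are irrelevant to the epoch-restricted CCG; drop them
    times = np.sort(np.concatenate(pieces)) if pieces else np.empty(0)
    return SpikeTrain(train.unit_id, times, train.t_start, train.t_end)


def jitter_baseline(a: SpikeTrain, b: SpikeTrain, epochs: EpochSet, label: str,
                    jitter_window: float = 0.5, reps: int = 3,
                    seed=None, bin_width: float = 0.005, max_lag: float = 1.0,
                    jitter_both: bool = False) -> CCG:
    """Baseline CCG from locally jittered spike trains, averaged over
    ``reps`` independent jitters.

    Interval jitter of one train within fixed 0.5 s partitions smears lag
    structure with a triangular kernel of 1 s total width, so this is the
    surrogate oracle for :func:`smooth_triangular`-based normalization.
    Jittering both trains (``jitter_both=True``) widens the effective kernel
    (triangle convolved with itself, 2 s support) and is kept as an option.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    acc = None
    for _ in range(reps):
        aj = jitter_spike_train(a, epochs, label, jitter_window, rng)
        bj = jitter_spike_train(b, epochs, label, jitter_window, rng) if jitter_both else b
        c = compute_ccg(aj, bj, epochs, label, bin_width, max_lag)
        acc = c if acc is None else replace(acc, counts=acc.counts + c.counts)
    return replace(acc, counts=acc.counts / reps, pair=(a.unit_id, b.unit_id))


def normalize_ccg(raw: CCG, baseline: CCG, pseudocount: float = 1.0,
                  variant: str = STANDARD) -> NormalizedCCG:
    """values = ln((raw + pseudocount) / (baseline + pseudocount)).

    The pseudocount bounds the log at empty bins; flat CCGs map to ~0.
    """
    if raw.lag_centers.size != baseline.lag_centers.size or not np.allclose(
            raw.lag_centers, baseline.lag_centers):
        raise ValueError("raw and baseline CCGs must share the same lag grid")
    values = np.log((raw.counts + pseudocount) / (baseline.counts + pseudocount))
    return NormalizedCCG(raw.pair, raw.lag_centers, values, variant=variant)


def dce_windows(lag_centers: np.ndarray, variant: str = STANDARD,
                center_halfwidth: float = 0.125, edge_width: float = 0.125):
    """Boolean masks of the center and edge bins for a DCE variant."""
    lag = lag_centers
    eps = 1e-9
    max_lag = float(lag[-1])
    center = np.abs(lag) <= center_halfwidth + eps
    if variant == STANDARD:
        if max_lag < 1.0 - eps:
            raise ValueError("STANDARD DCE requires max_lag >= 1 s")
        edge = np.abs(lag) >= max_lag - edge_width - eps
    elif variant == UP_ONLY:
        if max_lag < 2.0 - eps:
            raise ValueError("UP_ONLY DCE requires max_lag >= 2 s")
        edge = (np.abs(lag) >= 1.0 - eps) & (np.abs(lag) <= 2.0 + eps)
    else:
        raise ValueError(f"unknown DCE variant {variant!r}")
    return center, edge


def compute_dce(nccg: NormalizedCCG, variant: str | None = None,
                alpha: float = ALPHA, state_or_variant: str | None = None) -> DCEResult:
    """Center mean minus edge mean of the normalized CCG, with a Welch
    t-test between the two sets of bin values (significant iff p < alpha).

    STANDARD: center |lag| <= 125 ms, edges = outermost 125 ms of the lag
    range.  UP_ONLY: same center, edges at 1 s <= |lag| <= 2 s (the UP-state
    bell shape undershoots at the extreme lags after normalization).
    """
    variant = variant or nccg.variant
    center, edge = dce_windows(nccg.lag_centers, variant)
    if center.sum() < 2 or edge.sum() < 2:
        raise ValueError("fewer than 2 bins in a DCE window")
    cv = nccg.values[center]
    ev = nccg.values[edge]
    dce = float(cv.mean() - ev.mean())
    if np.ptp(cv) < 1e-12 and np.ptp(ev) < 1e-12:
        # numerically flat windows: no structure to test
        p = 1.0 if abs(dce) < 1e-12 else 0.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(stats.ttest_ind(cv, ev, equal_var=False).pvalue)
        if np.isnan(p):
            p = 1.0
    return DCEResult(nccg.pair, state_or_variant or variant, dce, p,
                     bool(p < alpha), n_center=int(center.sum()),
                     n_edge=int(edge.sum()))


def _crop(ccg: CCG, max_lag: float) -> CCG:
    m = np.abs(ccg.lag_centers) <= max_lag + 1e-9
    return replace(ccg, lag_centers=ccg.lag_centers[m], counts=ccg.counts[m],
                   max_lag=max_lag)


def triangular_baseline(a: SpikeTrain, b: SpikeTrain, epochs: EpochSet,
                        label: str, bin_width: float = 0.005,
                        max_lag: float = 1.0, smooth_window: float = 1.0
                        ) -> tuple[CCG, CCG]:
    """(raw, smoothed-baseline) CCG pair with the raw counts computed on a
    lag range extended by the kernel half-width so the baseline is unbiased
    at the outermost lags."""
    half_w = bin_width * np.ceil(0.5 * smooth_window / bin_width)
    raw_ext = compute_ccg(a, b, epochs, label, bin_width, max_lag + half_w)
    return (_crop(raw_ext, max_lag),
            _crop(smooth_triangular(raw_ext, smooth_window), max_lag))


def pair_dce(a: SpikeTrain, b: SpikeTrain, epochs: EpochSet, label: str,
             params: CCGParams | None = None, variant: str = STANDARD,
             seed=None) -> tuple[NormalizedCCG, DCEResult]:
    """Full raw -> baseline -> normalized -> DCE chain for one pair/state.

    With the triangular baseline the raw CCG is computed on a lag range
    extended by the kernel half-width, so the smoothed baseline at the
    outer (DCE edge) lags averages over real counts rather than a
    truncated, renormalized kernel.
    """
    params = params or CCGParams()
    if params.baseline == "jitter":
        raw = compute_ccg(a, b, epochs, label, params.bin_width,
                          params.max_lag)
        base = jitter_baseline(a, b, epochs, label, params.jitter_window,
                               params.jitter_reps, seed, params.bin_width,
                               params.max_lag)
    else:
        raw, base = triangular_baseline(a, b, epochs, label,
                                        params.bin_width, params.max_lag,
                                        params.smooth_window)
    nccg = normalize_ccg(raw, base, params.pseudocount, variant=variant)
    res = compute_dce(nccg, variant, params.alpha, state_or_variant=label)
    return nccg, res
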