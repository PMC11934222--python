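"""Seeded synthetic recordings with ground truth for every mechanism the
pipeline must recover.

The generator emulates a long (default 24 h) rodent frontal-cortex
recording: alternating wake / nonREM / REM bouts; UP/DOWN alternation at
0.5-4 Hz inside nonREM with strictly zero DOWN-state firing; per-unit
UP-phase firing profiles; and an LFP whose delta power is high in nonREM,
grows with epoch duration, and ramps up/down with duration-independent time
constants while gamma power anti-varies.

Units are organized in disjoint pairs; each pair carries one mechanism:

INDEPENDENT
    the two units fire independently from their UP-phase profiles.
COACTIVE
    a shared event train adds near-coincident (~20 ms jitter) spikes to
    both units, producing a CCG peak.
ANTIPHASE
    within each UP state one unit occupies the early fraction and the other
    the late fraction, with the side randomly swapped from UP to UP.  The
    occupancy fraction interpolates with an anticorrelation *strength*
    (1 = strict halves, 0 = full overlap = independent) that is coupled to
    the per-epoch delta amplitude.  Averaged statistics are unaffected; the
    trough exists only in simultaneous per-UP dynamics.
BURSTY_ANTIPHASE
    the anti-phased component is emitted as short bursts (3-5 spikes,
    3-8 ms ISIs) on top of an independent non-burst component, so burst
    removal selectively destroys the anticorrelation.

During wake a configurable fraction of anti-phased pairs keeps an
attenuated slot-based anticorrelation (troughs do occur in wake, at roughly
half the rate and lower amplitude); REM is structureless, so trough
incidence ranks nonREM > wake > REM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import EpochSet, SpikeTrain
from .lfp import LFP

INDEPENDENT = "INDEPENDENT"
COACTIVE = "COACTIVE"
ANTIPHASE = "ANTIPHASE"
BURSTY_ANTIPHASE = "BURSTY_ANTIPHASE"
CLASSES = (INDEPENDENT, COACTIVE, ANTIPHASE, BURSTY_ANTIPHASE)


@dataclass
class SyntheticConfig:
    """Study conditions of a synthetic recording.

    Durations in seconds, rates in Hz.  The defaults describe a 24 h
    recording of 40 units (20 disjoint pairs) with the class mixture
    80% independent / 12% coactive / 8% anti-phased (half of the
    anti-phased pairs bursty).
    """

    duration_h: float = 24.0
    n_units: int = 40
    seed: int = 0

    # state schedule: lognormal bout durations (median, sigma of log)
    wake_median_s: float = 220.0
    wake_sigma: float = 0.5
    nrem_median_s: float = 300.0
    nrem_sigma: float = 0.6
    rem_median_s: float = 100.0
    rem_sigma: float = 0.4
    min_bout_s: float = 30.0

    # UP/DOWN alternation inside nonREM (~0.65 Hz, brief DOWN silences)
    up_median_s: float = 1.5
    up_sigma: float = 0.4
    up_range: tuple = (0.3, 3.0)
    down_median_s: float = 0.06
    down_sigma: float = 0.3
    down_range: tuple = (0.04, 0.3)
    up_taper_s: float = 0.0    # optional graded UP onset/offset ramp length

    # unit roster; default profiles are uniform over UP phase so that
    # averaged statistics carry no shared sub-second structure (biased
    # profiles, e.g. Beta(1, 3), reintroduce the averaged-statistics peak)
    rate_range_hz: tuple = (2.0, 20.0)  # UP-state rates, log-uniform
    profile_a_range: tuple = (1.0, 1.0)  # Beta shape over UP phase
    profile_b_range: tuple = (1.0, 1.0)

    # pair classes
    class_fractions: dict = field(default_factory=lambda: {
        INDEPENDENT: 0.80, COACTIVE: 0.12, ANTIPHASE: 0.04,
        BURSTY_ANTIPHASE: 0.04})

    # mechanism parameters
    coactive_fraction: float = 0.3
    coactive_jitter_s: float = 0.05
    antiphase_strength: float = 0.7     # baseline anticorrelation strength
    delta_coupling: float = 0.35        # strength units per SD of delta amp
    strength_range: tuple = (0.2, 1.0)
    pair_strength_range: tuple = (0.8, 1.0)  # stable per-pair depth scale
    wake_trough_fraction: float = 0.5   # anti-phased pairs structured in wake
    wake_attenuation: float = 0.6       # wake anti-modulation depth (0-1)
    wake_osc_hz: tuple = (1.2, 1.8)     # wake anti-modulation frequency
    burst_fraction: float = 0.8         # bursty pairs: rate share in bursts
    burst_size_range: tuple = (3, 5)
    burst_isi_range_s: tuple = (0.003, 0.008)

    # LFP
    lfp_rate_hz: float = 250.0
    delta_freq_hz: float = 4.0
    gamma_freq_hz: float = 55.0
    delta_base: float = 1.0
    gamma_base_nrem: float = 0.3
    delta_dur_slope: float = 0.5        # per relative epoch-duration excess
    gamma_dur_slope: float = 0.35
    drift_amp: float = 0.3              # slow multiplicative drift
    drift_period_s: float = 28800.0
    ramp_up_s: float = 60.0             # duration-independent ramps
    ramp_down_s: float = 25.0
    wake_delta: float = 0.1
    wake_gamma: float = 0.45
    rem_delta: float = 0.08
    rem_gamma: float = 0.5
    noise_sd: float = 0.2

    @property
    def duration_s(self) -> float:
        return self.duration_h * 3600.0

    @property
    def n_pairs(self) -> int:
        return self.n_units // 2

    def validate(self):
        if self.n_units < 2 or self.n_units % 2:
            raise ValueError("n_units must be an even number >= 2")
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-6:
            raise ValueError("class fractions must sum to 1")
        if any(v < 0 for v in self.class_fractions.values()):
            raise ValueError("class fractions must be nonnegative")
        if self.rate_range_hz[0] <= 0:
            raise ValueError("rates must be positive")
        mean_burst_span = (np.mean(self.burst_size_range) - 1) * \
            np.mean(self.burst_isi_range_s)
        if mean_burst_span >= self.up_range[0]:
            raise ValueError("burst span exceeds the shortest UP duration")


@dataclass
class GroundTruth:
    """Per-pair class labels and per-epoch latent variables."""

    pair_classes: pd.DataFrame    # unit_a, unit_b, pair_class, wake_structured
    states: EpochSet
    updown: EpochSet
    nrem_epochs: pd.DataFrame     # start, end, duration, delta_amp, gamma_amp,
                                  # antiphase_strength
    unit_rates: pd.Series         # configured UP-state rate per unit

    def pairs_of_class(self, *classes) -> list[tuple]:
        t = self.pair_classes[self.pair_classes["pair_class"].isin(classes)]
        return [(r.unit_a, r.unit_b) for r in t.itertuples()]

    @property
    def all_pairs(self) -> list[tuple]:
        return [(r.unit_a, r.unit_b) for r in self.pair_classes.itertuples()]


@dataclass
class SyntheticRecording:
    trains: list
    states: EpochSet
    updown: EpochSet
    lfp: LFP
    truth: GroundTruth
    config: SyntheticConfig


# ---------------------------------------------------------------- schedule

def generate_state_schedule(config: SyntheticConfig,
                            rng: np.random.Generator) -> EpochSet:
    """Alternating WAKE -> NREM -> REM bouts until the recording ends."""
    T = config.duration_s
    specs = [("WAKE", config.wake_median_s, config.wake_sigma),
             ("NREM", config.nrem_median_s, config.nrem_sigma),
             ("REM", config.rem_median_s, config.rem_sigma)]
    t = 0.0
    ivs = []
    i = 0
    while t < T:
        label, med, sig = specs[i % 3]
        d = max(config.min_bout_s, med * np.exp(sig * rng.standard_normal()))
        d = min(d, T - t)
        if d >= config.min_bout_s:
            ivs.append((t, t + d, label))
        t += d
        i += 1
    return EpochSet.from_tuples(ivs)


def generate_up_down(config: SyntheticConfig, nrem_starts, nrem_ends,
                     rng: np.random.Generator) -> EpochSet:
    """UP/DOWN alternation within each nonREM epoch (starts with UP)."""
    ivs = []
    for s, e in zip(nrem_starts, nrem_ends):
        t = s
        is_up = True
        while t < e - 1e-9:
            if is_up:
                d = np.clip(config.up_median_s *
                            np.exp(config.up_sigma * rng.standard_normal()),
                            *config.up_range)
                lab = "UP"
                dmin = 0.1
            else:
                d = np.clip(config.down_median_s *
                            np.exp(config.down_sigma * rng.standard_normal()),
                            *config.down_range)
                lab = "DOWN"
                dmin = 0.05
            d = min(d, e - t)
            if d >= dmin:
                ivs.append((t, t + d, lab))
            t += d
            is_up = not is_up
    return EpochSet.from_tuples(ivs)


# -------------------------------------------------------------- primitives

def _grouped_cumsum(vals: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Cumulative sum restarting at each group boundary."""
    cs = np.cumsum(vals)
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    base = np.repeat(cs[starts] - vals[starts], sizes)
    return cs - base

def _mean_env(durs, ramp):
    """Mean of the boundary-taper envelope over an UP of given duration."""
    if ramp <= 0:
        return np.ones_like(durs)
    durs = np.asarray(durs, float)
    return np.where(durs >= 2 * ramp, 1.0 - ramp / durs,
                    durs / (4 * ramp))


def _taper_thin(t, up_start_of, up_dur_of, ramp, rng):
    """Keep each spike with probability of the onset/offset ramp envelope
    (linear ramps of fixed absolute length at both UP boundaries)."""
    if ramp <= 0 or t.size == 0:
        return np.ones(t.size, dtype=bool)
    rel = t - up_start_of
    env = np.clip(np.minimum(rel, up_dur_of - rel) / ramp, 0.0, 1.0)
    return rng.random(t.size) < env


def _profile_times(up_starts, up_durs, rate, bin_probs,
                   rng: np.random.Generator, ramp: float = 0.0) -> np.ndarray:
    """Inhomogeneous-Poisson spikes over UP states from a 50-bin profile,
    thinned by the boundary-taper envelope with rate compensation."""
    n = rng.poisson(rate * up_durs / _mean_env(up_durs, ramp))
    tot = int(n.sum())
    if tot == 0:
        return np.empty(0)
    nb = bin_probs.size
    bins = rng.choice(nb, size=tot, p=bin_probs)
    phase = (bins + rng.random(tot)) / nb
    s_of = np.repeat(up_starts, n)
    d_of = np.repeat(up_durs, n)
    t = s_of + phase * d_of
    return t[_taper_thin(t, s_of, d_of, ramp, rng)]


def _window_times(up_starts, up_durs, w_lo_frac, w_hi_frac, rate,
                  rng: np.random.Generator, ramp: float = 0.0) -> np.ndarray:
    """Uniform spikes in a per-UP phase window [w_lo, w_hi), preserving the
    whole-UP expected count rate*dur (before boundary tapering)."""
    n = rng.poisson(rate * up_durs / _mean_env(up_durs, ramp))
    s_of = np.repeat(up_starts, n)
    d_of = np.repeat(up_durs, n)
    lo = s_of + np.repeat(np.broadcast_to(w_lo_frac, up_durs.shape), n) * d_of
    hi = s_of + np.repeat(np.broadcast_to(w_hi_frac, up_durs.shape), n) * d_of
    t = lo + rng.random(int(n.sum())) * (hi - lo)
    return t[_taper_thin(t, s_of, d_of, ramp, rng)]


def _antiphase_windows(n_up, strengths, rng: np.random.Generator):
    """Per-UP occupancy windows for the two units: fractions of UP duration.

    strength 1 -> strict early/late halves; strength 0 -> full overlap.
    Sides swap at random from UP to UP.
    """
    f = 1.0 - strengths / 2.0          # occupancy fraction per UP
    early = rng.random(n_up) < 0.5
    a_lo = np.where(early, 0.0, 1.0 - f)
    a_hi = np.where(early, f, 1.0)
    b_lo = np.where(early, 1.0 - f, 0.0)
    b_hi = np.where(early, 1.0, f)
    return (a_lo, a_hi), (b_lo, b_hi)


def _burst_times(event_times, up_ends_of_events, config: SyntheticConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Expand burst events into 3-5 spike bursts, clipped at the UP end."""
    if event_times.size == 0:
        return np.empty(0)
    lo, hi = config.burst_size_range
    sizes = rng.integers(lo, hi + 1, size=event_times.size)
    tot = int(sizes.sum())
    isis = rng.uniform(*config.burst_isi_range_s, size=tot)
    first = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    isis[first] = 0.0
    offs = _grouped_cumsum(isis, sizes)
    t = np.repeat(event_times, sizes) + offs
    return t[t < np.repeat(up_ends_of_events, sizes)]


# ------------------------------------------------------------------ pairs

def _class_counts(fractions: dict, n_pairs: int) -> dict:
    """Largest-remainder apportionment of pair classes."""
    items = [(c, fractions.get(c, 0.0) * n_pairs) for c in CLASSES]
    counts = {c: int(np.floor(v)) for c, v in items}
    rem = sorted(items, key=lambda cv: cv[1] - np.floor(cv[1]), reverse=True)
    short = n_pairs - sum(counts.values())
    for c, _ in rem[:short]:
        counts[c] += 1
    return counts


def generate_pair(config: SyntheticConfig, pair_class: str, rates, profiles,
                  up_starts, up_durs, up_strengths,
                  rng: np.random.Generator):
    """NonREM (UP-state) spike times of one pair.  Expected per-unit rate
    within UP states equals the configured rate for every class."""
    ra, rb = rates
    pa, pb = profiles
    n_up = up_starts.size
    ramp = config.up_taper_s
    if pair_class == INDEPENDENT:
        ta = _profile_times(up_starts, up_durs, ra, pa, rng, ramp)
        tb = _profile_times(up_starts, up_durs, rb, pb, rng, ramp)
    elif pair_class == COACTIVE:
        cf = config.coactive_fraction
        shared_rate = cf * min(ra, rb)
        ev = _window_times(up_starts, up_durs, 0.0, 1.0, shared_rate, rng,
                           ramp)
        up_of_ev = np.searchsorted(up_starts, ev, side="right") - 1
        ends = up_starts[up_of_ev] + up_durs[up_of_ev]
        sa = np.clip(ev + rng.normal(0, config.coactive_jitter_s, ev.size),
                     up_starts[up_of_ev], ends - 1e-6)
        sb = np.clip(ev + rng.normal(0, config.coactive_jitter_s, ev.size),
                     up_starts[up_of_ev], ends - 1e-6)
        ta = np.concatenate([
            _profile_times(up_starts, up_durs, ra - shared_rate, pa, rng,
                           ramp), sa])
        tb = np.concatenate([
            _profile_times(up_starts, up_durs, rb - shared_rate, pb, rng,
                           ramp), sb])
    elif pair_class == ANTIPHASE:
        (alo, ahi), (blo, bhi) = _antiphase_windows(n_up, up_strengths, rng)
        ta = _window_times(up_starts, up_durs, alo, ahi, ra, rng, ramp)
        tb = _window_times(up_starts, up_durs, blo, bhi, rb, rng, ramp)
    elif pair_class == BURSTY_ANTIPHASE:
        bf = config.burst_fraction
        mean_size = float(np.mean(config.burst_size_range))
        (alo, ahi), (blo, bhi) = _antiphase_windows(n_up, up_strengths, rng)
        ta_list, tb_list = [], []
        for r, prof, (wlo, whi), out in ((ra, pa, (alo, ahi), ta_list),
                                         (rb, pb, (blo, bhi), tb_list)):
            out.append(_profile_times(up_starts, up_durs, (1 - bf) * r, prof,
                                      rng, ramp))
            ev = _window_times(up_starts, up_durs, wlo, whi,
                               bf * r / mean_size, rng, ramp)
            up_of_ev = np.searchsorted(up_starts, ev, side="right") - 1
            ends = up_starts[up_of_ev] + up_durs[up_of_ev]
            out.append(_burst_times(ev, ends, config, rng))
        ta = np.concatenate(ta_list)
        tb = np.concatenate(tb_list)
    else:
        raise ValueError(f"unknown pair class {pair_class!r}")
    return np.sort(ta), np.sort(tb)


# -------------------------------------------------------------------- LFP

def _epoch_latents(config: SyntheticConfig, states: EpochSet,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Per-nonREM-epoch delta/gamma amplitudes and antiphase strengths."""
    s, e = states.select("NREM")
    dur = e - s
    mid = 0.5 * (s + e)
    rel = (dur - config.nrem_median_s) / config.nrem_median_s
    drift = config.drift_amp * np.sin(2 * np.pi * mid / config.drift_period_s)
    delta = config.delta_base * (1 + config.delta_dur_slope * rel) * (1 + drift)
    delta = np.maximum(delta, 0.1 * config.delta_base)
    gamma = config.gamma_base_nrem * (1 - config.gamma_dur_slope * rel) * \
        (1 - drift)
    gamma = np.maximum(gamma, 0.05 * config.gamma_base_nrem)
    z = (delta - delta.mean()) / delta.std() if delta.std() > 0 else \
        np.zeros_like(delta)
    strength = np.clip(config.antiphase_strength + config.delta_coupling * z,
                       *config.strength_range)
    return pd.DataFrame({"start": s, "end": e, "duration": dur,
                         "delta_amp": delta, "gamma_amp": gamma,
                         "antiphase_strength": strength})


def generate_lfp(config: SyntheticConfig, states: EpochSet,
                 nrem_table: pd.DataFrame, rng: np.random.Generator) -> LFP:
    """Delta + gamma oscillations with per-epoch amplitudes, fixed-length
    onset/offset ramps, and a white noise floor."""
    fs = config.lfp_rate_hz
    n = int(round(config.duration_s * fs))
    x = rng.normal(0, config.noise_sd, n).astype(np.float32)
    t_all = np.arange(n) / fs

    def add_epoch(s, e, amp_d, amp_g, ramped):
        i0, i1 = int(s * fs), min(int(e * fs), n)
        if i1 <= i0:
            return
        t = t_all[i0:i1]
        if ramped:
            env = (1 - np.exp(-(t - s) / config.ramp_up_s)) * \
                  (1 - np.exp(-(e - t) / config.ramp_down_s))
        else:
            env = 1.0
        x[i0:i1] += (amp_d * env * np.sin(2 * np.pi * config.delta_freq_hz * t)
                     + amp_g * env *
                     np.sin(2 * np.pi * config.gamma_freq_hz * t)
                     ).astype(np.float32)

    for row in nrem_table.itertuples():
        add_epoch(row.start, row.end, row.delta_amp, row.gamma_amp, True)
    for s, e, lab in states.to_tuples():
        if lab == "WAKE":
            add_epoch(s, e, config.wake_delta, config.wake_gamma, False)
        elif lab == "REM":
            add_epoch(s, e, config.rem_delta, config.rem_gamma, False)
    return LFP(x, fs, 0.0)


# ------------------------------------------------------------------ driver

def generate_recording(config: SyntheticConfig | None = None,
                       seed=None) -> SyntheticRecording:
    """Fully seeded synthetic recording with ground truth.

    ``seed`` overrides ``config.seed``; all randomness flows from it.
    """
    config = config or SyntheticConfig()
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    states = generate_state_schedule(config, rng)
    updown = generate_up_down(config, *states.select("NREM"), rng)
    nrem_table = _epoch_latents(config, states, rng)

    up_starts, up_ends = updown.select("UP")
    up_durs = up_ends - up_starts
    # antiphase strength of the nonREM epoch each UP state belongs to
    ep_idx = np.searchsorted(nrem_table["start"].to_numpy(), up_starts,
                             side="right") - 1
    up_strengths = nrem_table["antiphase_strength"].to_numpy()[ep_idx]

    n_pairs = config.n_pairs
    counts = _class_counts(config.class_fractions, n_pairs)
    classes = sum(([c] * counts[c] for c in CLASSES), [])
    classes = [classes[i] for i in rng.permutation(n_pairs)]

    lo, hi = config.rate_range_hz
    rates = np.exp(rng.uniform(np.log(lo), np.log(hi), config.n_units))
    phase = (np.arange(50) + 0.5) / 50.0
    prof_a = rng.uniform(*config.profile_a_range, config.n_units)
    prof_b = rng.uniform(*config.profile_b_range, config.n_units)
    profiles = [phase ** (a - 1) * (1 - phase) ** (b - 1)
                for a, b in zip(prof_a, prof_b)]
    profiles = [p / p.sum() for p in profiles]

    anti_idx = [i for i, c in enumerate(classes)
                if c in (ANTIPHASE, BURSTY_ANTIPHASE)]
    n_wake = int(round(config.wake_trough_fraction * len(anti_idx)))
    wake_structured = set(anti_idx[:n_wake])

    w_starts, w_ends = states.select("WAKE")
    r_starts, r_ends = states.select("REM")
    nrem_total = states.total_duration("NREM")
    up_total = float(up_durs.sum())

    width = len(str(config.n_units - 1))
    unit_ids = [f"u{i:0{width}d}" for i in range(config.n_units)]
    trains = []
    truth_rows = []
    for p in range(n_pairs):
        ia, ib = 2 * p, 2 * p + 1
        cls = classes[p]
        pair_scale = rng.uniform(*config.pair_strength_range)
        ta, tb = generate_pair(config, cls, (rates[ia], rates[ib]),
                               (profiles[ia], profiles[ib]),
                               up_starts, up_durs,
                               np.clip(up_strengths * pair_scale, 0.0, 1.0),
                               rng)
        # wake/REM: homogeneous Poisson matched to the unit's nonREM rate;
        # wake-structured anti-phased pairs instead share a slot pattern
        slot_seed = int(rng.integers(2 ** 31))
        trains_pair = []
        for k, (iu, t_nrem) in enumerate(((ia, ta), (ib, tb))):
            r_match = rates[iu] * up_total / nrem_total
            if p in wake_structured:
                t_wake = _wake_pair_member(
                    w_starts, w_ends, r_match,
                    config.wake_attenuation * pair_scale,
                    k == 0, config, np.random.default_rng(slot_seed), rng)
            else:
                t_wake = _poisson_in_epochs(w_starts, w_ends, r_match, rng)
            t_rem = _poisson_in_epochs(r_starts, r_ends, r_match, rng)
            trains_pair.append((iu, t_nrem, t_wake, t_rem))
        for iu, t_nrem, t_wake, t_rem in trains_pair:
            times = np.sort(np.concatenate([t_nrem, t_wake, t_rem]))
            times = times[(times >= 0) & (times < config.duration_s)]
            trains.append(SpikeTrain(unit_ids[iu], times, 0.0,
                                     config.duration_s))
        truth_rows.append((unit_ids[ia], unit_ids[ib], cls,
                           p in wake_structured))

    lfp = generate_lfp(config, states, nrem_table, rng)
    truth = GroundTruth(
        pd.DataFrame(truth_rows, columns=["unit_a", "unit_b", "pair_class",
                                          "wake_structured"]),
        states, updown, nrem_table,
        pd.Series(rates, index=unit_ids, name="up_rate_hz"))
    return SyntheticRecording(trains, states, updown, lfp, truth, config)


def _poisson_in_epochs(starts, ends, rate, rng: np.random.Generator):
    durs = ends - starts
    n = rng.poisson(rate * durs)
    return np.repeat(starts, n) + rng.random(int(n.sum())) * np.repeat(durs, n)


def _wake_pair_member(starts, ends, rate, depth, is_first,
                      config: SyntheticConfig, g_osc, rng):
    """One unit of a wake-structured pair: slow anti-phased sinusoidal rate
    modulation, rate*(1 +/- depth*sin(2*pi*f*t + phi)), with per-epoch
    frequency and phase shared across the pair (from ``g_osc``)."""
    sign = 1.0 if is_first else -1.0
    out = []
    for s, e in zip(starts, ends):
        f = g_osc.uniform(*config.wake_osc_hz)
        phi = g_osc.uniform(0, 2 * np.pi)
        lam_max = rate * (1 + depth)
        n = rng.poisson(lam_max * (e - s))
        t = s + rng.random(n) * (e - s)
        lam = rate * (1 + sign * depth * np.sin(2 * np.pi * f * t + phi))
        keep = rng.random(n) * lam_max < lam
        out.append(t[keep])
    return np.concatenate(out) if out else np.empty(0)
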