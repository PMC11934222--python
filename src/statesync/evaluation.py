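"""End-to-end property evaluations of the pipeline on synthetic data.

Each function generates its own inputs (analytic spike trains or synthetic
recordings with ground truth), runs the relevant pipeline stages from
scratch, and returns a dict of named scalar results.  They are used by the
acceptance test suite and by ``scripts/acceptance.py``; problem sizes are
chosen so the full set runs in minutes on one CPU (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .burst import (BURST_PERCENT, BURST_THRESHOLD, RANDOM,
                    fit_log_isi_mixture, removal_sweep)
from .ccg import (CCG, CCGParams, compute_dce, jitter_baseline,
                  normalize_ccg, pair_dce, smooth_triangular,
                  triangular_baseline)
from .core import EpochSet, SpikeTrain
from .lfp import (DELTA_BAND, GAMMA_BAND, dce_stability_matrix,
                  epoch_duration_power_correlation, quartile_dce_power,
                  trough_pair_selection, windowed_dce_power_correlation)
from .state import state_dce_table
from .synth import (ANTIPHASE, BURSTY_ANTIPHASE, COACTIVE, INDEPENDENT,
                    SyntheticConfig, generate_recording)
from .upstate import (dce_null_from_simulation, scrambled_up_dce,
                      simulate_profile_pair, up_only_dce, up_spike_profile,
                      up_timing_metrics, timing_metric_contrast)


def _sub_seeds(seed, n):
    return [int(s) for s in
            np.random.default_rng(seed).integers(2 ** 31, size=n)]


# ------------------------------------------------------------- calibration

def null_calibration(seed=1, n_pairs: int = 200, duration: float = 2000.0,
                     rate_range=(2.0, 5.0)) -> dict:
    """False-positive rate of the DCE test on independent Poisson pairs,
    plus exactness of the flat-CCG zero."""
    rng = np.random.default_rng(seed)
    ep = EpochSet.from_tuples([(0.0, duration, "NREM")])
    n_sig = 0
    for _ in range(n_pairs):
        ra, rb = rng.uniform(*rate_range, size=2)
        a = SpikeTrain("a", np.sort(rng.uniform(0, duration,
                                                rng.poisson(ra * duration))),
                       0, duration)
        b = SpikeTrain("b", np.sort(rng.uniform(0, duration,
                                                rng.poisson(rb * duration))),
                       0, duration)
        _, res = pair_dce(a, b, ep, "NREM")
        n_sig += res.significant
    grid = np.arange(-200, 201) * 0.005
    flat = CCG(("x", "y"), grid, np.full(grid.size, 37.0), 0.005, 1.0, 1)
    nccg = normalize_ccg(flat, smooth_triangular(flat))
    flat_dce = abs(compute_dce(nccg).dce)
    return {"null_sig_pct": 100.0 * n_sig / n_pairs,
            "flat_dce_abs": float(flat_dce), "n_pairs": n_pairs}


def _antiphase_recording(seed, n_units, duration_h, strength=0.95,
                         classes=None, **kw):
    config = SyntheticConfig(
        duration_h=duration_h, n_units=n_units, seed=seed,
        class_fractions=classes or {INDEPENDENT: 0.0, COACTIVE: 0.0,
                                    ANTIPHASE: 1.0, BURSTY_ANTIPHASE: 0.0},
        antiphase_strength=strength, delta_coupling=0.0,
        strength_range=(strength, strength), pair_strength_range=(1.0, 1.0),
        wake_trough_fraction=0.0, **kw)
    return generate_recording(config, seed=seed)


def oracle_agreement(seed=1, n_pairs: int = 60, reps: int = 30,
                     min_abs_dce: float = 0.2,
                     duration_h: float = 0.75) -> dict:
    """Triangular-convolution vs interval-jitter normalization agreement.

    DCE per pair under both baselines on anti-phased pairs; relative error
    reported over pairs whose jitter-based |DCE| exceeds ``min_abs_dce``.
    """
    rec = _antiphase_recording(seed, 2 * n_pairs, duration_h)
    params = CCGParams()
    rel = []
    seeds = _sub_seeds(seed, n_pairs)
    by_id = {t.unit_id: t for t in rec.trains}
    for (ua, ub), s in zip(rec.truth.all_pairs, seeds):
        a, b = by_id[ua], by_id[ub]
        raw, tri = triangular_baseline(a, b, rec.states, "NREM",
                                       params.bin_width, params.max_lag)
        d_tri = compute_dce(normalize_ccg(raw, tri))
        base = jitter_baseline(a, b, rec.states, "NREM", reps=reps, seed=s)
        d_jit = compute_dce(normalize_ccg(raw, base))
        if abs(d_jit.dce) > min_abs_dce:
            rel.append(abs(d_tri.dce - d_jit.dce) / abs(d_jit.dce))
    rel = np.asarray(rel)
    return {"n_qualifying_pairs": int(rel.size),
            "max_rel_err_pct": float(100 * rel.max()),
            "median_rel_err_pct": float(100 * np.median(rel))}


# --------------------------------------------------------------- recovery

def mechanism_recovery(seed=1, n_seeds: int = 3,
                       duration_h: float = 6.0) -> dict:
    """Trough recovery and state rank order on the default class mixture."""
    trough_counts = {"NREM": 0, "WAKE": 0, "REM": 0}
    n_troughs = 0
    n_true = 0
    n_pairs_total = 0
    for s in range(seed, seed + n_seeds):
        config = SyntheticConfig(duration_h=duration_h, seed=s)
        rec = generate_recording(config, seed=s)
        table = state_dce_table(rec.trains, rec.states,
                                pairs=rec.truth.all_pairs)
        m = table.merge(rec.truth.pair_classes, on=["unit_a", "unit_b"])
        n_pairs_total += len(rec.truth.all_pairs)
        for st in trough_counts:
            sub = m[(m.state == st) & m.significant & (m.dce < 0)]
            trough_counts[st] += len(sub)
            if st == "NREM":
                n_troughs += len(sub)
                n_true += sub.pair_class.isin(
                    [ANTIPHASE, BURSTY_ANTIPHASE]).sum()
    recovery = 100.0 * n_true / n_troughs if n_troughs else float("nan")
    pct = {st: 100.0 * c / n_pairs_total for st, c in trough_counts.items()}
    return {"trough_recovery_pct": recovery,
            "trough_pct_nrem": pct["NREM"], "trough_pct_wake": pct["WAKE"],
            "trough_pct_rem": pct["REM"],
            "rank_order_holds": float(pct["NREM"] > pct["WAKE"] > pct["REM"]),
            "n_nrem_troughs": n_troughs}


def profile_resimulation(seed=1, n_pairs: int = 50,
                         duration_h: float = 1.0,
                         n_null_sims: int = 100) -> dict:
    """Averaged-statistics resimulation cannot produce troughs.

    Anti-phased pairs are resimulated from their averaged 50-bin UP
    profiles on the recording's own UP/DOWN durations; the share of
    resimulations with a significant negative DCE is reported (expected 0)
    together with a z-test of one pair's real DCE against its 100-sim null.
    """
    rec = _antiphase_recording(seed, 2 * n_pairs, duration_h)
    by_id = {t.unit_id: t for t in rec.trains}
    starts, ends = rec.updown.select("UP")
    ds, de = rec.updown.select("DOWN")
    durations = sorted(
        [(s, "UP", e - s) for s, e in zip(starts, ends)]
        + [(s, "DOWN", e - s) for s, e in zip(ds, de)])
    updown_durations = [(lab, d) for _, lab, d in durations]
    sim_seeds = _sub_seeds(seed, n_pairs)
    n_real_neg = n_sim_neg_sig = 0
    first_pair_z = first_pair_p = None
    for i, (ua, ub) in enumerate(rec.truth.all_pairs):
        a, b = by_id[ua], by_id[ub]
        _, real = up_only_dce(a, b, rec.updown)
        pa = up_spike_profile(a, rec.updown)
        pb = up_spike_profile(b, rec.updown)
        sa, sb, ep = simulate_profile_pair(pa, pb, updown_durations,
                                           seed=sim_seeds[i])
        _, sim = up_only_dce(sa, sb, ep)
        n_real_neg += real.significant and real.dce < 0
        n_sim_neg_sig += sim.significant and sim.dce < 0
        if i == 0:
            _, _, z, p, _ = dce_null_from_simulation(
                pa, pb, updown_durations, real.dce, n_sims=n_null_sims,
                seed=sim_seeds[i])
            first_pair_z, first_pair_p = z, p
    return {"sim_neg_sig_pct": 100.0 * n_sim_neg_sig / n_pairs,
            "real_neg_sig_pct": 100.0 * n_real_neg / n_pairs,
            "null_z": first_pair_z, "null_z_p": first_pair_p,
            "n_pairs": n_pairs}


def upnext_scrambling(seed=1, n_trough_pairs: int = 50,
                      n_peak_pairs: int = 25,
                      duration_h: float = 1.0) -> dict:
    """UPnext scrambling destroys troughs and reduces peaks.

    Non-negativity uses the zero-when-not-significant convention for the
    scrambled DCE.
    """
    rec_t = _antiphase_recording(seed, 2 * n_trough_pairs, duration_h)
    rec_p = _antiphase_recording(
        seed + 1, 2 * n_peak_pairs, duration_h,
        classes={INDEPENDENT: 0.0, COACTIVE: 1.0, ANTIPHASE: 0.0,
                 BURSTY_ANTIPHASE: 0.0})
    out = {}
    # trough pairs
    by_id = {t.unit_id: t for t in rec_t.trains}
    n_neg = n_nonneg_after = 0
    for ua, ub in rec_t.truth.all_pairs:
        orig, scram = scrambled_up_dce(by_id[ua], by_id[ub], rec_t.updown)
        if orig.significant and orig.dce < 0:
            n_neg += 1
            n_nonneg_after += scram.effective_dce >= 0
    out["n_trough_pairs"] = n_neg
    out["scrambled_nonneg_pct"] = (100.0 * n_nonneg_after / n_neg
                                   if n_neg else float("nan"))
    # peak pairs
    by_id = {t.unit_id: t for t in rec_p.trains}
    orig_pos, scram_pos = [], []
    for ua, ub in rec_p.truth.all_pairs:
        orig, scram = scrambled_up_dce(by_id[ua], by_id[ub], rec_p.updown)
        if orig.significant and orig.dce > 0:
            orig_pos.append(orig.dce)
            scram_pos.append(scram.effective_dce)
    orig_pos, scram_pos = np.asarray(orig_pos), np.asarray(scram_pos)
    out["n_peak_pairs"] = int(orig_pos.size)
    out["peak_mean_orig"] = float(orig_pos.mean()) if orig_pos.size else np.nan
    out["peak_mean_scrambled"] = (float(scram_pos.mean())
                                  if orig_pos.size else np.nan)
    out["peak_reduced"] = float(orig_pos.size > 0
                                and scram_pos.mean() < orig_pos.mean())
    out["peak_sign_flips"] = int((scram_pos < 0).sum())
    return out


def timing_contrast(seed=1, n_per_group: int = 30,
                    duration_h: float = 2.0) -> dict:
    """Trough pairs show larger SD of per-UP spike-time differences than
    peak pairs."""
    classes = {INDEPENDENT: 0.0, COACTIVE: 0.5, ANTIPHASE: 0.5,
               BURSTY_ANTIPHASE: 0.0}
    rec = _antiphase_recording(seed, 4 * n_per_group, duration_h,
                               classes=classes)
    table = state_dce_table(rec.trains, rec.states,
                            pairs=rec.truth.all_pairs)
    by_id = {t.unit_id: t for t in rec.trains}
    metrics = [up_timing_metrics(by_id[ua], by_id[ub], rec.updown)
               for ua, ub in rec.truth.all_pairs]
    rep = timing_metric_contrast(metrics, table)
    rep = rep.set_index("metric")
    return {"p_sd_first": float(rep.loc["sd_diff_first", "p"]),
            "p_sd_mean": float(rep.loc["sd_diff_mean", "p"]),
            "sd_first_trough": float(rep.loc["sd_diff_first", "trough_mean"]),
            "sd_first_peak": float(rep.loc["sd_diff_first", "peak_mean"]),
            "n_trough": int(rep.loc["sd_diff_first", "n_trough"]),
            "n_peak": int(rep.loc["sd_diff_first", "n_peak"])}


def burst_removal_effect(seed=1, n_pairs: int = 30,
                         duration_h: float = 1.5,
                         levels=(0.0, 0.25, 0.5, 0.75, 1.0)) -> dict:
    """Burst removal weakens anticorrelation more than matched random
    removal; threshold-sweep and percent modes are indistinguishable."""
    rec = _antiphase_recording(
        seed, 2 * n_pairs, duration_h,
        classes={INDEPENDENT: 0.0, COACTIVE: 0.0, ANTIPHASE: 0.0,
                 BURSTY_ANTIPHASE: 1.0})
    by_id = {t.unit_id: t for t in rec.trains}
    models = {t.unit_id: fit_log_isi_mixture(t) for t in rec.trains}
    n_bimodal = sum(m.bimodal for m in models.values())
    sweep_seeds = _sub_seeds(seed, n_pairs)
    modes = (BURST_THRESHOLD, BURST_PERCENT, RANDOM)
    per_mode = {m: [] for m in modes}      # per-pair mean ratio
    slope_mode = {m: [] for m in modes}    # per-pair ratio-vs-level slope
    for (ua, ub), s in zip(rec.truth.all_pairs, sweep_seeds):
        a, b = by_id[ua], by_id[ub]
        _, orig = pair_dce(a, b, rec.states, "NREM")
        if not (orig.significant and orig.dce < 0):
            continue
        res = removal_sweep(a, b, rec.states, models, seed=s, levels=levels)
        df = pd.DataFrame([{"mode": r.mode, "level": r.level,
                            "ratio": r.dce_ratio} for r in res])
        for mode in modes:
            sub = df[df["mode"] == mode]
            per_mode[mode].append(sub[sub["level"] > 0]["ratio"].mean())
            slope_mode[mode].append(
                stats.linregress(sub["level"], sub["ratio"]).slope)
    thr = np.asarray(per_mode[BURST_THRESHOLD])
    pct = np.asarray(per_mode[BURST_PERCENT])
    rnd = np.asarray(per_mode[RANDOM])

    def mwu(x, y):
        # the per-pair collections are compared as unpaired samples
        return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)

    return {"n_pairs_used": int(thr.size), "n_bimodal_units": int(n_bimodal),
            "mean_ratio_burst_threshold": float(thr.mean()),
            "mean_ratio_burst_percent": float(pct.mean()),
            "mean_ratio_random": float(rnd.mean()),
            "p_threshold_vs_random": mwu(thr, rnd),
            "p_percent_vs_random": mwu(pct, rnd),
            "p_threshold_vs_percent": mwu(thr, pct),
            "p_slope_threshold_vs_random": mwu(
                slope_mode[BURST_THRESHOLD], slope_mode[RANDOM]),
            "p_slope_threshold_vs_percent": mwu(
                slope_mode[BURST_THRESHOLD], slope_mode[BURST_PERCENT])}


def lfp_modulation(seed=1, n_pairs: int = 20,
                   duration_h: float = 12.0) -> dict:
    """Delta power positively and gamma power negatively modulate |DCE|
    (3-h windows, epoch quartiles and epoch-duration correlations)."""
    config = SyntheticConfig(
        duration_h=duration_h, n_units=2 * n_pairs, seed=seed,
        class_fractions={INDEPENDENT: 0.0, COACTIVE: 0.0, ANTIPHASE: 1.0,
                         BURSTY_ANTIPHASE: 0.0},
        antiphase_strength=0.6, delta_coupling=0.45,
        pair_strength_range=(0.75, 1.0), wake_trough_fraction=0.0)
    rec = generate_recording(config, seed=seed)
    table = state_dce_table(rec.trains, rec.states,
                            pairs=rec.truth.all_pairs)
    pairs = trough_pair_selection(table)
    bands = [DELTA_BAND, GAMMA_BAND]
    wrep = windowed_dce_power_correlation(rec.trains, rec.states, rec.lfp,
                                          bands, pairs).set_index("f_lo")
    _, q_r, q_p = quartile_dce_power(rec.trains, rec.states, rec.lfp,
                                     DELTA_BAND, pairs)
    drep = epoch_duration_power_correlation(rec.states, rec.lfp,
                                            bands).set_index("f_lo")
    stab = dce_stability_matrix(rec.trains, rec.states, table,
                                n_units=min(20, 2 * n_pairs), seed=seed)
    return {"n_trough_pairs": len(pairs),
            "window_R_delta": float(wrep.loc[DELTA_BAND[0], "R"]),
            "window_p_delta": float(wrep.loc[DELTA_BAND[0], "p"]),
            "window_R_gamma": float(wrep.loc[GAMMA_BAND[0], "R"]),
            "window_p_gamma": float(wrep.loc[GAMMA_BAND[0], "p"]),
            "quartile_R_delta": float(q_r), "quartile_p_delta": float(q_p),
            "duration_R_delta": float(drep.loc[DELTA_BAND[0], "R"]),
            "duration_R_gamma": float(drep.loc[GAMMA_BAND[0], "R"]),
            "stability_z": float(stab.z),
            "stability_real_sd": float(stab.mean_sd),
            "stability_shuffled_sd": float(stab.shuffled_mean)}


def determinism_check(seed=1, tmpdir=None) -> dict:
    """Two `run-all` pipeline runs with the same seed are byte-identical."""
    import filecmp
    import tempfile
    from pathlib import Path

    from click.testing import CliRunner

    from .cli import main as cli_main

    base = Path(tmpdir or tempfile.mkdtemp(prefix="statesync_det_"))
    cfg = {"duration_h": 1.0, "n_units": 8,
           "class_fractions": {INDEPENDENT: 0.5, COACTIVE: 0.25,
                               ANTIPHASE: 0.25, BURSTY_ANTIPHASE: 0.0}}
    import yaml
    cfg_path = base / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh)
    runner = CliRunner()
    dirs = []
    for run in ("run1", "run2"):
        out = base / run
        r = runner.invoke(cli_main, ["run-all", "--config", str(cfg_path),
                                     "--seed", str(seed), "--out", str(out)])
        if r.exit_code != 0:
            raise RuntimeError(f"run-all failed: {r.output}\n{r.exception}")
        dirs.append(out)
    files = sorted(p.name for p in dirs[0].iterdir())
    match, mismatch, errors = filecmp.cmpfiles(dirs[0], dirs[1], files,
                                               shallow=False)
    return {"identical": float(not mismatch and not errors),
            "n_files": len(files), "n_mismatched": len(mismatch)}
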