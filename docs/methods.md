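# Methods

This note documents the statistical procedures implemented in `statesync`,
the defaults and the reasoning behind them, what the synthetic generator
does and does not emulate, and the numerical choices that matter for
reproducing results.

## CCG accumulation

The cross-correlogram of a unit pair is the histogram of lags
`t_b − t_a` over spike pairs that fall inside the *same* labeled epoch;
per-epoch histograms are summed over all epochs of a state.  Epochs are
half-open `[start, end)` and epochs sharing a label may not overlap.
Internally, epochs are remapped onto a common axis with dead gaps wider
than the lag range, so one vectorized pass over the concatenated trains is
exactly equivalent to per-epoch CCGs.

Defaults: **bin width 5 ms**, **lag range ±1 s** (±2 s for UP-state-only
CCGs).  The 5 ms bin makes the 250 ms center window and the 125 ms edge
windows contain whole bins (51 and 2×26).  The lag grid is symmetric with
a bin centered at zero; lags are assigned by rounding to the nearest bin
center, which makes `ccg(a,b)` exactly the lag-reversal of `ccg(b,a)`.
Epochs shorter than the lag span are allowed (UP states usually are); the
normalization absorbs the resulting bell shape.

## Normalization and the DCE

Raw CCGs are divided by a slow baseline and log-transformed:

```
values = ln((raw + 1) / (baseline + 1))
```

The pseudocount of 1 in numerator and denominator bounds the log at empty
bins; a perfectly flat CCG maps to exactly zero.  Note the pseudocount
shrinks log-ratios toward zero when per-bin counts are small — estimates
from fewer spikes are mildly conservative, which matters when comparing
spike-removal conditions.

Two baselines are provided:

* **Triangular convolution** (default): the raw CCG convolved with a
  unit-area triangular window of 1 s total width.  The raw CCG is computed
  on a lag range extended by the kernel half-width and cropped after
  smoothing, so the baseline at the outermost (edge-window) lags averages
  real counts rather than a truncated, renormalized kernel — without the
  extension the edge baseline is biased exactly where the DCE reads it.
* **Interval jitter** (the surrogate oracle): one train's spikes are
  re-drawn uniformly within fixed 0.5 s partitions anchored at each epoch
  start, the CCG recomputed, and the average over repetitions (default 3;
  ≥ 20 for oracle comparisons) used as the baseline.  Jittering one train
  in 0.5 s windows smears lag structure with a triangular kernel of 1 s
  support, hence the equivalence of the two baselines; jittering *both*
  trains would convolve the triangle with itself (2 s support) and is kept
  only as an option.  The test suite checks that the two baselines agree
  in DCE within 10% relative error on strongly anti-phased pairs.

**DCE** = mean normalized value in the center window (|lag| ≤ 125 ms)
minus the mean over the edge windows (outermost 125 ms of the ±1 s range;
1 s ≤ |lag| ≤ 2 s for the UP-only variant, whose bell-shaped CCGs
undershoot at extreme lags).  Significance is a two-sample
unequal-variance (Welch) t-test between center-window and edge-window bin
values at **α = 10⁻⁴** (the test flavor is a package choice; only "t test"
is prescribed by the source analysis).  Windows that are numerically flat
(range < 10⁻¹²) are treated as untestable and non-significant.  Population
summaries treat non-significant DCE as zero.

Because the t-test compares bin values *within* windows, it is sensitive
to window-shape heterogeneity: a very narrow peak (≪ 125 ms) inflates the
center-window variance and can be less significant than a broad peak of
the same mean — a property to keep in mind when interpreting borderline
pairs.

## State pipeline

`StateSynchrony(trains, states).fit()` computes the pair × state DCE
table.  Derived summaries:

* trough/peak percentages per state (significant negative / positive DCE
  over all pairs);
* state-specificity crosstab: for each ordered state pair (X, Y), the
  percentage of pairs with significant negative DCE in X and
  non-significant ("zero") DCE in Y;
* |DCE| comparison across states for pairs significant in all (or one
  named) state: one-way ANOVA with Tukey-HSD-corrected pairwise p-values;
* matched downsampling: whole epochs of the longer states are drawn at
  random without replacement until their cumulative duration first reaches
  the shortest state's total (stopping at first crossing, overshoot below
  one epoch — simpler than trimming partial epochs and unbiased in
  expectation); pooled in-epoch spike counts are then thinned to the
  common minimum; DCE is averaged over (default 3) repetitions with
  majority-vote significance.

## UP-state analyses

* **Detection** (optional; curated epochs pass through unchanged):
  population spike counts in 10 ms bins, boxcar-smoothed over 3 bins;
  DOWN = maximal runs below 10% of the mean nonREM population rate
  lasting ≥ 50 ms; UP = complementary intervals ≥ 100 ms.
* **UP-only DCE**: CCGs restricted to UP epochs (DOWN spikes never
  counted), ±2 s lags, edges at 1–2 s.  An optional per-UP duration trim
  matches the scrambled control.
* **UPnext scrambling**: unit a's spikes in UP state N (as offsets from
  its onset, in absolute seconds — not phase-rescaled) are re-anchored at
  UP N−1's onset; each receiving UP is trimmed to the lesser of the two
  durations, overhanging spikes dropped, and the partner analyzed on the
  same trimmed epochs.  This preserves each unit's per-UP statistics while
  destroying simultaneous within-UP structure.
* **UP-phase profiles**: each UP's spikes are binned into 50 equal phase
  bins, converted to a probability distribution, and averaged over UP
  states (UPs with zero spikes are skipped — counting them as zero vectors
  would bias profiles toward sparse UPs' shapes).
* **Profile resimulation**: pairs are re-simulated from their averaged
  profiles as independent inhomogeneous Poisson processes on an UP/DOWN
  schedule (phase-bin rate = `mean_rate_up · 50 · bin_probs`, zero in
  DOWN), and an observed DCE is z-tested against the DCE distribution of
  (default 100) such simulations.
* **Timing metrics**: per UP state where both units fire, the difference
  in first and in mean spike time (a − b, seconds from UP onset); the mean
  and SD across UPs summarize each pair; pairs with < 10 qualifying UPs
  are flagged.  Trough-vs-peak group contrasts use two-sided Mann–Whitney
  tests; per-pair "consistent lag" fractions use one-sample t-tests on the
  per-UP differences.

## Burst analysis

A two-component Gaussian mixture is fit to a unit's log₁₀ ISIs
(scikit-learn, 3 restarts, fixed random state).  A unit is **bimodal**
only if the component means are ≥ 1 log₁₀(s) apart and neither component
is degenerate.  The **separatrix** is the minimum of the mixture density
between the means (0.001 log₁₀-s scan); the **burst threshold** is
`10^(μ_fast + 2σ_fast)`, capped at the separatrix.  **Burst spikes** are
maximal runs of ≥ 3 consecutive spikes whose successive ISIs are all below
threshold; entire runs are removed including the first spike (the
`keep_run_head` option spares it — the source text is ambiguous on this
point, and the choice is configurable).

Removal sweeps scale the threshold by levels 0–1; per level the
count-matched controls remove the same number of spikes either as a random
subset of base-threshold burst spikes (percent mode) or anywhere within
the nonREM epochs (random mode).  The readout is the **DCE ratio**
(post/original: > 1 amplified, 0–1 reduced, < 0 reversed).  Mode
comparisons collect per-pair means and slopes of the ratio-vs-level curves
and compare the collections with unpaired Mann–Whitney tests.  Note the
ordering check uses the ratio rather than raw |DCE|: with heavy spike
removal the log-ratio magnitude of deep troughs is inflated by the
low-count bias of the logarithm, so raw post-removal |DCE| can slightly
exceed the original even when the ratio correctly shows no effect.

## LFP analyses

Band power is a sliding-window Welch estimate (1 s windows, half overlap),
integrated per band, optionally restricted to epochs of one state, and
z-scored over time with |z| > 3 outliers excluded; the exclusion is
iterated until the outlier set stabilizes, which makes the normalization
idempotent.  The default band grid is 20 log-spaced bands over
0.5–100 Hz plus the two named example bands 3.5–4.3 Hz (delta) and
49–60 Hz (gamma).

* **Windowed correlation**: recordings are cut into 3 h windows (anchored
  at the start; final partial window kept if ≥ 1 h); per window and
  trough pair a nonREM-only DCE is computed, and per band the Spearman
  correlation between |DCE| (or signed DCE in sign-split mode) and the
  window's mean normalized nonREM band power, pooled over pairs and
  windows.  Bands with < 10 points or zero power variance are flagged.
* **Quartiles**: nonREM epochs ranked by mean band power into four
  quartiles (stable tie-break); per pair and quartile a DCE from that
  quartile's epochs alone; Pearson correlation of quartile power vs DCE.
* **Duration/power**: for nonREM epochs > 200 s, mean band power over
  `[start+120 s, end−50 s]` (excluding the duration-independent ramps)
  against epoch duration, Pearson per band.
* **Stability**: the most anticorrelated units (default 20) and their
  trough pairs form a pair × 3-h-window DCE matrix; the mean across pairs
  of the per-pair SD over windows is z-tested against the distribution
  from 200 within-window shuffles across pairs.

## The synthetic generator

`SyntheticConfig` defaults describe a 24 h recording of 40 units in 20
disjoint pairs.  What it emulates — and deliberately does not:

* **State schedule**: repeating wake → nonREM → REM bouts with lognormal
  durations (medians 220 / 300 / 100 s), giving REM the least total time.
* **UP/DOWN**: alternation inside nonREM at ~0.65 Hz (UP lognormal median
  1.5 s clipped to 0.3–3 s; DOWN median 60 ms clipped to 40–300 ms),
  strictly zero DOWN firing.  Brief DOWN states and (by default) uniform
  UP-phase profiles are essential: shared on/off gating with deep DOWN
  silences, graded shared onset ramps, or shared early-phase profile bias
  all produce *genuine* positive normalized-CCG centers for independent
  pairs — this is precisely the "averaged statistics predict positive
  correlation" effect, reproducible here via `profile_b_range` or
  `up_taper_s`.  The defaults keep independent pairs null so that
  mechanism recovery is well-defined.
* **Pair mechanisms**: the class mixture is 80% independent, 12% coactive
  (shared events, ~50 ms jitter → CCG peak), 4% anti-phased and 4% bursty
  anti-phased.  Anti-phased pairs occupy opposite fractions of each UP
  with sides swapped at random per UP — averaged statistics are unchanged,
  only simultaneous per-UP dynamics carry the trough (variable timing, no
  consistent lag; a fixed-lag mechanism would contradict the observation
  that consistent lags do not differ between trough and peak pairs).  The
  occupancy fraction interpolates with an anticorrelation strength coupled
  to the per-epoch delta amplitude, times a stable per-pair depth scale
  (0.8–1.0) that gives pairs individual identities (needed for any
  temporal-stability contrast to be meaningful).  Bursty pairs emit the
  anti-phased component as 3–5-spike bursts (3–8 ms ISIs, 80% of rate) on
  top of an independent non-burst component, so burst removal selectively
  deletes the anticorrelation.
* **Wake/REM**: homogeneous Poisson matched to each unit's nonREM mean
  rate.  Half of the anti-phased pairs additionally carry an attenuated
  anti-phased sinusoidal rate modulation (1.2–1.8 Hz, depth 0.6 × the
  pair scale) during wake: troughs do occur in wake at roughly half the
  nonREM incidence and lower amplitude, which yields the observed
  nonREM > wake > REM trough ranking.  REM is structureless.
* **LFP**: 250 Hz; 4 Hz delta and 55 Hz gamma sinusoids with white noise.
  Per-nonREM-epoch delta amplitude grows with epoch duration and a slow
  (8 h) drift; gamma anti-varies; both ramp with fixed time constants
  (60 s up, 25 s down) regardless of epoch duration; wake/REM have low
  delta and moderate gamma.  The anti-phase strength tracks the per-epoch
  delta amplitude, so delta power positively (and gamma negatively)
  modulates trough depth by construction.
* **Not emulated**: spike sorting artifacts, cell-type structure,
  non-stationary rates within states, theta/spindle oscillations, realistic
  1/f LFP spectra, and wake behavioral structure.  Passing tests therefore
  demonstrate that the *pipeline* recovers planted mechanisms under the
  stated noise model — not that real recordings contain them.

Determinism: all randomness flows from a single integer seed through one
`numpy` generator (stage seeds derived from it); identical seeds give
byte-identical outputs, which the test suite checks at the file level.

## Problem sizes

The evaluation suite (`statesync.evaluation`, used by
`tests/test_acceptance.py` and `scripts/acceptance.py`) chooses sizes that
keep the whole set within a few minutes on one CPU while leaving the
statistical margins comfortable: 200 Poisson pairs × 2000 s for null
calibration; 60 anti-phased pairs (0.75 h, 30 jitter repetitions) for the
baseline-equivalence check; the default 40-unit mixture at 6 h for three
seeds for mechanism recovery; 50 pairs (1 h) for resimulation and UPnext;
30 + 30 pairs (2 h) for timing contrasts; 30 bursty pairs (1.5 h) for
removal sweeps; 20 delta-coupled pairs over 12 h for the LFP analyses; and
a 1 h / 8-unit pipeline for the determinism check.  Recovery and ranking
results are insensitive to extending these toward the full 24 h defaults;
only runtimes change.

## Known limitations

* The DCE t-test treats normalized bins as independent samples; smoothing
  in the baseline induces weak bin correlations, making the test slightly
  conservative or liberal depending on structure width.  The null
  calibration keeps the realized false-positive rate well under the
  nominal bound at α = 10⁻⁴.
* UP-only normalized CCGs of short UP states retain a positive gating
  offset even after division (both center and 1–2 s edges sit on the bell
  shape); comparisons are therefore made within matched conditions
  (original vs scrambled on identical trimmed epochs) rather than against
  an absolute zero.
* The GMM burst model assumes at most two log-ISI modes; units with
  multi-modal ISI structure get a conservative `bimodal=False`.
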