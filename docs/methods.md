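# Methods

## Scope and data model

The package analyses dual-channel fluorescence recordings of *C. elegans*
male mating bouts and the behavioral records scored alongside them. A
recording is a `DualChannelTrace`: strictly increasing sample times (seconds
from recording start), per-frame ROI mean gray levels for the green
(G-CaMP) and red (mDsRed) channels, and matched background ROI series.
Behavioral events (`EventLog`) share the recording clock; all intervals are
half-open `[start, end)` and durations are `end − start`. Undefined metrics
propagate as explicit missing values, never zeros.

## Ratiometric correction

The red reference is Ca²⁺-insensitive, so any trend in it is an artifact —
dominated by photobleaching over the minute-scale bouts analysed here.
Among decay families, a mono-exponential with offset,
`red(t) = A·exp(−t/τ) + c`, is the standard single-fluorophore bleaching
model and is the default (`PipelineConfig.bleach_model`); the offset
absorbs the non-bleaching background of the fluorophore pool. The fit is
plain least squares (`scipy.optimize.curve_fit`) with bounds keeping all
parameters non-negative; constant input returns the degenerate model
(amplitude 0, `tau = nan`). On noiseless exponentials the parameters are
recovered to better than one part in 10⁶ (tested).

Correction divides out the *relative* decay, normalised to the model value
at t = 0: `red_corr = red · model(0)/model(t)`. Normalising to t = 0 keeps
the early-recording baseline — where F0 is taken — unbiased. The green
channel is not detrended (G-CaMP bleaching is negligible on this
timescale). The ratio `r = green/red_corr` is converted to percent change
relative to `F0`, the mean of `r` over a window preceding the first
insertion event; the window is the 2 s before insertion by default
(`f0_span_s`), or all pre-insertion samples when fewer are available. By
construction the mean of `%ΔF/F0` over the F0 window is zero to 10⁻⁹.
Whether the original analyses ratioed green over adjusted red or adjusted
the ratio itself is ambiguous; green over corrected red is implemented, and
because the correction is multiplicative the two differ only by the
normalisation point, which the t = 0 convention pins down.

Background-subtracted values are clipped at zero (gray levels are
non-negative); a clip affecting more than 1% of samples is logged.
Restrained-male (single-channel) recordings use `single_channel_dff`, which
normalises green against its own baseline, and `restrained_summary`, which
reports the largest |%ΔF/F0| excursion from the value at time 0 and the SD
over a one-minute window.

## Event-aligned kinetics

*Onset* is not defined in the source analyses beyond "where the Ca²⁺ begins
to increase"; the rule used here is: first time after the alignment event at
which `%ΔF/F0` exceeds baseline mean + k·SD (k = 2) and stays above it for
m = 3 consecutive samples, backtracked to the last preceding sample at or
below the baseline mean. The backtrack matters: the raw threshold crossing
lags the true onset by ≈ k·SD/slope (≈ 0.2 s for a 45 %/s rise at 3%
per-channel noise), while the backtracked estimate is unbiased to within a
few hundredths of a second (tested on synthetic cohorts).

*Peak latency* is the argmax of `%ΔF/F0` in a window after insertion
(default 30 s, spanning intromission through sperm release), ties broken to
the earliest sample — latency is a minimum-time quantity. The search runs
on a lightly smoothed copy (centred moving average, 5 samples ≈ 0.25 s at
20 Hz) and reports the raw argmax within ±5 samples of the smoothed one.
Without this step, the argmax of a small transient over a 30 s window
occasionally lands on an isolated noise excursion tens of seconds from the
transient, which single-handedly corrupts a cohort mean; with it, noiseless
traces still yield the exact raw argmax and the estimator stays unbiased
for the waveforms generated here (locally symmetric apex). Slopes are
always fit on the raw, unsmoothed trace.

*Rise slope* is the OLS straight-line slope of `%ΔF/F0` against time over
[onset, peak]. *Post-peak slope* is the OLS slope over the 15 s following
the global maximum (the window spans sperm release); a truncated window is
fit on the available samples and flagged.

*Biphasic traces* (sex muscles): the first/second-peak distinction requires
the first *local* maximum, not the global argmax — the second, ejaculatory
contraction can exceed the first. The first peak is declared once the trace
has declined below its running maximum by 20% of that maximum (at least
6 baseline SD, so noise dips on a steep rise do not trigger it). The second
rise is then detected on a 0.55 s-smoothed copy as a sustained increase of
k·SD above the running minimum after the first peak, with a 2·k·SD
prominence guard; its slope is fit from the threshold crossing (the noisy
flat bottom around the minimum would otherwise dilute it). The measured
second-rise slope estimates the *net* rate of the observed trace — the
underlying rise rate minus the concurrent slow decay of the first
transient — and per-bout estimates are heavy-tailed, so cohort-level
comparisons against generator truth use the median.

*Cohort summaries* report mean ± sample SD (n − 1 denominator) with n per
feature, excluding bouts for which a feature is undefined.

## Synthetic data generator

The generator emulates the recording conditions the pipeline was built for:
a baseline bout with an insertion-triggered transient, mDsRed bleaching,
and additive noise.

**Waveform.** Linear rise (optionally sigmoidal) from onset to the peak
amplitude, then a two-component decline: a fast relaxation toward a
sustained fraction of the peak plus a slow linear return to baseline
(`decay_rate`, %ΔF/F0 per s). The fast component's time constant defaults
to `(1 − sustained_fraction)·rise_duration`, which makes the transient
leave its apex at the same initial rate it rose. This shape reflects
sustained-activity indicator recordings (a rounded apex relaxing onto an
elevated plateau that then declines slowly) rather than a kinked
rise-then-plateau, whose nearly flat post-peak region would make the peak
time ill-determined at realistic noise. Optional components: a delayed
second rise (biphasic muscle dynamics) and a damped post-release
oscillation.

**Presets.** Cohort kinetics are parameterised per cell class: mean ± SD of
the insertion→peak latency and of the initial rise slope (SPC 1.3 ± 0.52 s,
45 ± 13 %/s; valve 1.8 ± 0.79 s, 60 ± 14 %/s; SPV/SPD 4.0 ± 1.0 s,
21 ± 14 %/s; PCA 6.3 ± 0.56 s, 15 ± 2.9 %/s; socket cells 1.7 ± 0.36 s,
94 ± 18 %/s; sex muscles first peak 1.3 ± 1.7 s, 155 ± 82 %/s, second peak
11 ± 3.9 s, 46 ± 19 %/s; plus control/ablated SPC variants, a weak-PCB
preset, a flat dopaminergic-ray preset, and a slow-decay valve preset for
the spicule-tips-cut phenotype). Peak amplitude is slope × rise duration.
The valve preset emits a `valve_open` event 6.9 ± 1.5 s after insertion.
Red bleaching uses τ = 60 s toward a floor of 0.3 of the initial level;
noise is additive Gaussian per sample and channel at 3% of the channel
baseline by default; the frame interval defaults to 0.05 s (20 Hz) —
acquisition rate and recording length are free parameters, since neither is
pinned by the source material.

**Cohorts.** Per-bout latency and slope are drawn from moment-matched
lognormals (positive, right-skewed quantities) with the preset mean/SD,
clipped at mean + 4 SD — the unbounded upper tail produces
multi-thousand-percent transients that are unphysical. Insertion times are
jittered uniformly in a documented window (4–6 s). Per-bout seeds derive
from the master seed via `SeedSequence(seed, spawn_key=(1+i,))`; the
parameter draws use `spawn_key=(0,)`, so `cohort_ground_truth` replays them
exactly without re-simulating. All generators are pure functions of
(parameters, seed).

**Trial populations.** `simulate_trials` emulates scored mating cohorts:
commencement, insertion latency, first-insertion duration (≈ 94 s),
refractory period (lognormal, 720 ± 390 s — the ~12 min mean with ~6.5 min
SD), transfer duration (≈ 17 s), and outcome categories driven by
`p_insert`, `p_valve_open` and `p_release`. Second-mating siring success
increases with the refractory period (sperm-reserve recovery), which is the
effect the 3–8:59 vs 9–30 min refractory binning probes.

**What the generator does not emulate.** Motion artifacts, ROI tracking
error beyond the explicit drift-path fixture, correlated or multiplicative
noise, indicator saturation, and z-drift. Passing recovery tests therefore
demonstrates correctness of the analysis chain under the stated noise
model, not robustness to every artifact of real recordings.

## Statistics

Implemented from first principles so that printed p-values on printed
tables are reproducible exactly; scipy supplies only reference
distributions and serves as an independent oracle in the tests.

* **Fisher's exact test** enumerates all tables with the observed margins
  using exact integer binomial coefficients; the two-sided p is the total
  probability of tables whose point probability is ≤ the observed one
  (probability-mass rule). This definition — not mid-p, not tail-doubling —
  reproduces the published contingency p-values (0.0377, 0.0005, 0.0078,
  0.0498, 0.6, < 0.0001). Degenerate margins give p = 1 with a warning.
* **Mann–Whitney U** uses midranks; the exact two-sided p enumerates all
  group assignments (counting assignments with |U − n₁n₂/2| at least the
  observed) when n₁+n₂ ≤ 16 with no ties, otherwise a tie-corrected normal
  approximation with 0.5 continuity correction. The two modes agree within
  0.02 at n = 8 vs 8 (tested over 100 draws).
* **Paired t**, one-way **ANOVA** with **Newman–Keuls** (stepwise
  studentized-range procedure, quantiles evaluated numerically from
  `scipy.stats.studentized_range`, harmonic-mean SE for unequal n, with the
  standard blocking rule) or **Bonferroni** (pooled-MSE pairwise t, p ×
  number of comparisons, capped at 1), and a two-sided **variance-ratio**
  test (larger variance in the numerator). Whether a printed
  "F value = 0.0009" denotes a statistic or a p-value is ambiguous in the
  source; the procedure is implemented as the test and the ambiguity left
  open.
* p-values are never rounded internally; rounding happens only at
  presentation.

Note on the Newman–Keuls simulation check: with one separated group among
three, the two "involving" pairs are detected essentially always, but the
null pair is tested at ≈ α once the wide range is significant, so ~5% of
simulated cohorts flag it; the test asserts power ≥ 99/100 and false flags
≤ 10/100 rather than a perfect pattern.

## Behavioral scoring conventions

* Sperm-transfer ranking: outcome category (0 uterine ejaculation, 1 insert
  without ejaculation, 2 ectopic ejaculation, 3 neither) + time-to-insert /
  300 s; males that never insert within the 5 min observation contribute
  the full 1.0 time term (censored at the cap), keeping the ranking
  monotone within and across categories.
* Refractory binning splits at 540 s with half-open convention
  [180, 540) vs [540, 1800]; out-of-range trials are flagged, not dropped.
* Time at vulva truncates the contact during which insertion occurred at
  the insertion time (whether it should count fully is unspecified in the
  source; truncation is flagged by the interval-clipping rule).
* The 2nd-insert metrics clip inserted time to [2nd insert, +30 s] and
  count insert/retract events in the 60 s after the 2nd insert, excluding
  the anchor insert itself.

## Numerical and reproducibility choices

* Time is seconds from recording start; 0-based frame indexing; CSV files
  are comma-separated UTF-8 with a mandatory header; floats are written at
  full shortest-round-trip precision and parsed with pandas'
  `float_precision="round_trip"`, so write→read is lossless.
* Every pipeline run writes a log with the configuration digest
  (SHA-256 of the canonical YAML), the seed and the package version;
  identical invocations are byte-identical (tested).
* Tie-breaks: earliest sample at peaks; argmax of NumPy already returns the
  first maximal index, which the tests pin.
* Degenerate inputs: constant red → degenerate bleach model (identity
  correction); zero-variance paired differences → error; empty margins →
  p = 1 with warning; fewer than 2 bouts → no cohort summary.

## Problem sizes

Recovery tests and the acceptance script use 100-bout cohorts of 45 s
(60 s for biphasic muscle traces) at 20 Hz with 3% per-channel noise —
cohort-mean latencies then carry a standard error of SD/10, comfortably
resolving the sub-second latency differences between cell classes. The
Fisher type-I check uses 10⁴ null tables; Monte-Carlo cell-mean checks use
10⁴ draws.

## Known limitations

* The transient waveform is a stylised piecewise model; kinetics extracted
  from real recordings with saturating indicators or movement artifacts
  will carry biases the synthetic tests cannot reveal.
* The onset rule is threshold-based; for rise slopes below ~10 %ΔF/F0 per
  second at 3% noise, onset estimates degrade before latency estimates do.
* Newman–Keuls controls the familywise error only weakly (a property of
  the procedure itself, reproduced faithfully).
* The Mann–Whitney exact mode enumerates all C(n₁+n₂, n₁) assignments and
  is intended for the small cohort sizes (n ≤ 8 per group) it is used at.
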