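# spiculate

Quantitative analysis of *C. elegans* male copulation recordings: dual-channel
ratiometric Ca²⁺ trace correction, event-aligned transient kinetics,
mating-ethogram scoring, and the exact statistics used on the resulting
contingency outcomes.

## Who this is for

Researchers quantifying genetically encoded Ca²⁺ indicator recordings of the
male mating circuit — the SPC/SPV/SPD spicule neurons, the post-cloacal
sensilla (PCA/PCB/PCC), the spicule socket cells, the gonadal valve and the
sex muscles — together with the behavioral readouts that accompany them
(spicule insertion, sperm transfer, the post-ejaculatory refractory period).
Every stage is exercised on synthetic data with known ground truth, so the
whole pipeline is testable without any recordings.

## The model at its core

Recordings carry a Ca²⁺-sensitive green channel (G-CaMP) and a
Ca²⁺-insensitive red reference (mDsRed) as per-frame ROI mean gray levels,
plus matched background ROIs. The correction chain is

1. per-frame background subtraction per channel;
2. a mono-exponential bleach fit to the red reference,
   `red(t) = A·exp(−t/τ) + c` (G-CaMP bleaching is negligible over a bout,
   mDsRed bleaching is not);
3. bleach correction `red_corr(t) = red(t)·model(0)/model(t)`;
4. the ratiometric signal `r(t) = green(t)/red_corr(t)` expressed as
   `%ΔF/F0 = 100·(r(t) − F0)/F0`, with `F0` the mean of `r` over the 2 s
   preceding the first spicule insertion.

From the `%ΔF/F0` trace, event-aligned kinetics are extracted per bout:
onset (baseline mean + 2 SD, sustained), insertion→peak latency (argmax in a
30 s window), the initial rise slope (OLS over onset→peak, %ΔF/F0 per s),
optional biphasic second-rise features, and the slope over the 15 s after
the highest transient (which spans sperm release). Behavioral scoring
implements the sperm-transfer ranking (outcome category 0–3 plus
time-to-insert/300 s), the refractory period (1st→2nd spicule insertion),
drive, vulva and insertion metrics, the ≥10 s sustained-transfer criterion
and per-insertion potency. The statistics module implements Fisher's exact
test (two-sided, probability-mass rule, exact integer arithmetic),
Mann–Whitney U (exact enumeration for small samples), the paired t test,
one-way ANOVA with Newman–Keuls or Bonferroni pairwise comparisons, and the
two-sided variance-ratio test — from first principles, with scipy used only
for reference distributions.

## Worked example

```python
import spiculate as sp

# one synthetic SPC-neuron bout: insertion at 5 s, 45 s at 20 Hz, 3% noise
trace, events = sp.simulate_bout(sp.make_preset("spc"),
                                 insertion_time_s=5.0, duration_s=45.0,
                                 dt_s=0.05, seed=1)
result = sp.BoutKinetics(trace, events).fit()
print(result.summary())
```

```
Bout kinetics
============================================
samples                        900
baseline F0 (ratio)         1.0007
red bleach tau (s)           63.54
onset (s)                    5.050
insertion→peak (s)           1.200
peak ΔF/F0 (%)              63.037
rise slope (%/s)            43.330
post-peak 15 s slope        -2.745
```

The fitted bleach time constant (63.5 s vs the generator's 60 s), the
latency of 1.20 s after the 5 s insertion and the 43.3 %/s rise slope are
single-bout estimates of the preset's 1.3 ± 0.52 s latency and 45 ± 13 %/s
slope. At cohort scale the estimates tighten:

```python
bouts = sp.simulate_cohort(sp.make_preset("spc"), n=100, seed=11)
print(sp.CohortKinetics(bouts, "spc").fit().summary())
```

```
Cohort 'spc' (n = 100)
============================================
insertion→peak (s)      1.3 ± 0.5
initial rise slope (%/s) 44 ± 12
```

The same chain is available from the shell: `spiculate simulate bout`,
`spiculate process`, `spiculate kinetics`, `spiculate score-trials`,
`spiculate stats fisher 12 1 8 7`, `spiculate report table1`.

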