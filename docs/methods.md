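# Methods

## The measurement model

Frontal alpha asymmetry is defined here on the anterior-frontal pair of a
14-channel 10–20 montage:

    FAA = mean over windows of [ ln powR − ln powL ]

where `powL`/`powR` are the mean alpha-band (8–13 Hz, band edges inclusive)
power densities of AF3/AF4 in one Hann-tapered window. Windows are
`nperseg = 256` samples (2 s at 128 Hz, 0.5 Hz resolution) with 50 %
overlap. The window length is a package choice: it guarantees at least two
full windows in the shortest (5 s) analysis interval while still resolving
the alpha band. Two readings of the "mean" are possible and both are
implemented behind `log_mode`:

* `log_mean` (default): average the per-window log-power differences;
* `mean_log`: average band powers over windows first, one log ratio.

They agree exactly whenever the right/left power ratio is constant across
windows (the synthetic ground truth) and differ only through window noise
otherwise. FAA is antisymmetric under channel exchange and invariant under
any common positive rescaling of both channels — both properties are
enforced by tests.

## Interval schemes and SWB alignment

A score reported at time *t* is treated as valid on the half-open block
`[t − P/2, t + P/2)`, with `P` the report period; the first block therefore
starts at `P/2`. Scheme 1 uses one block-length interval centred on each
report; scheme 2 uses intervals of length L per report, either `[t − L, t]`
(`side=end`) or `[t − L/2, t + L/2]` (`side=center`); scheme 3 tiles the
run with disjoint length-L intervals anchored at `P/2` and labels each with
the overlap-weighted mean score, rounded half away from zero (a 5.5 tie
rounds to 6 — "nearest integer" alone does not fix the tie, so the
convention is stated here and tested). Intervals that would extend past
either end of the recording are dropped; with reports at `k·P` the final
report's centred interval never fits, so a 300 s run at `P = 30` yields 9
pairs under scheme 1 and 10 under scheme 2 `side=end`. Sample indices use
the half-open convention `[round(t₀·fs), round(t₁·fs))`.

## Preprocessing

Stage order is fixed and short-circuiting: load EDF (EEG channels only,
labels normalised to 10–20 names) → downsample 256→128 Hz → duration gate
(inclusive: 15.0 s passes) → linear detrend → bad-channel detection →
AF3/AF4 guard. The anti-alias filter is a zero-phase order-8 Butterworth
low-pass at 57.6 Hz (0.9× the target Nyquist) followed by decimation.

Bad-channel detection scores each channel by the mean over 1 Hz to
min(125 Hz, Nyquist) of the log Welch PSD and flags channels more than 3
cross-channel standard deviations from the mean, twice, removing flags
between passes (so a moderate outlier masked by an extreme one is caught on
the second pass). Averaging *log* PSD over frequencies (rather than log of
the average) makes the feature sensitive to broadband gain faults (a 10×
noise channel is lifted by ln 100 ≈ 4.6) but nearly blind to a legitimate
narrowband alpha peak, which only lifts a few of ~127 bins; on clean
synthetic runs AF3/AF4 sit near |z| ≈ 2.4–2.9, below the threshold. The
detection needs at least 4 channels and is invariant to channel order. If
AF3 or AF4 is flagged the run is excluded (`faa_channel_bad`); other bad
channels are dropped and the run continues.

Component-level artifact removal (wavelet-ICA, automatic IC classification)
is deliberately out of scope: those are external published pipelines, and
the synthetic data is generated either clean or with burst artifacts that
the interval schemes themselves are tested against.

## The statistics chain

Per participant: pairs whose SWB class has fewer than 3 members are
removed; participants with fewer than 3 surviving distinct scores are
excluded (`too_few_unique_swb`). SMOTE then oversamples every class to the
majority count on the one-dimensional FAA feature: a synthetic value is
`x + u·(x_nn − x)` with `u ~ U(0,1)`, `x` a uniformly drawn class member
and `x_nn` one of its `k = min(5, n_class − 1)` nearest same-class
neighbours (1-D distance, ties broken by lower index). Originals are never
removed and labels never change; synthetic values lie inside their class's
range by construction. Because SMOTE is stochastic, (balance → OLS) is run
10 times on independent substreams and the slopes/intercepts averaged; 10
repeats are enough for the average to stabilise well inside the
between-repeat scatter. OLS is the closed-form fit of FAA on SWB
(`np.polyfit`); scikit-learn's `LinearRegression` serves as an independent
cross-check in the tests only.

Group level: left-handed participants are removed by default (lateralised
measures are not comparable across handedness and the package does not
model the difference), then a one-sample t-test of the mean averaged slope
against 0 with alternative *mean > 0*; the one-sided 95 % confidence region
is `[mean − t₀.₉₅,df·SE, ∞)`. The reported mean pair count averages the
post-filter, pre-SMOTE counts of included participants. No multiplicity
correction is applied across the (L, side) grid — each cell reports its raw
one-sided p-value, mirroring how such grids are usually tabulated; readers
comparing many cells should correct accordingly.

## The synthetic generator

Each run is `run_duration_s` = 300 s at `fs` = 128 Hz (256 Hz supported)
with a report every `report_period_s` = 30 s. The SWB trajectory is a
mean-reverting integer random walk: steps are rounded draws from
N(0.35·(7 − s), 1²), clipped to ±2 and to [1, 10]. This concentrates the
marginal distribution on scores 6–8 — exactly the imbalance the SMOTE stage
exists to correct — while changing gradually between reports, as verbal
comfort ratings do. The concentration parameters are plausibility choices,
not calibrated to any dataset.

AF3 carries a 10 Hz sinusoid of amplitude 20 μV; within each SWB block AF4
carries amplitude `A_R = A_L·exp((a + b·s + ε)/2)`, `ε ~ N(0, noise_sd²)`,
so the planted log-power difference is exactly `a + b·s + ε` (power scales
with amplitude squared; with noise off, extraction recovers the line to
machine precision, far inside the 1e-2 spectral-leakage budget). Defaults
`a = 0`, `b = 0.1`, `noise_sd = 0.5` put the per-participant slope standard
error near 0.04 at ~90 pairs — a regime where a 27-participant cohort
detects the coupling with essentially full power while a null cohort
(`b = 0`) stays at the nominal 5 % rejection rate. All other channels are
Gaussian noise (5 μV SD); channels listed as bad get 10× noise amplitude;
optional artifact bursts add 200 μV noise for 2 s centred on each report
time, emulating movement while speaking. One master `SeedSequence` spawns
per-participant, then per-run substreams, so any run is reproducible in
isolation and regeneration is bit-identical.

What the generator does **not** emulate: 1/f background spectra, eye-blink
or EMG waveforms, electrode drift, volume conduction between channels, or
any physiological link between environment and brain signal — the
environment enters only through the SWB trajectory. Passing tests therefore
validate the *pipeline* (segmentation, spectral estimation, imbalance
correction, inference), not the neuroscientific claim on real recordings.

EEG is written as classic EDF (16-bit, 1 s records, fixed ±3276.8 μV range
→ exact 0.1 μV quantisation, fixed start stamp for byte-identical
regeneration) and read back through MNE.

## Problem sizes and numerical conventions

The simulation studies in the test suite run the full chain at the study's
cohort scale — 27 participants × 10 runs × 300 s per replicate, 50
replicates for power and 200 for null calibration — generating only the two
asymmetry channels, clean, so the per-replicate cost stays near two
seconds. The on-disk determinism check uses a 5-participant × 2-run cohort
over the full 6-cell (L, side) grid. Degenerate inputs fail loudly rather
than silently: zero band power in any window, fewer than 4 channels for
bad-channel detection, fewer than 2 distinct predictor values in OLS, fewer
than 2 usable participants or zero slope variance in the group test, and
subsampling caps that exceed availability all raise `ValueError`.

## Known limitations

* The bad-channel statistic is a z-score of average log power, a
  deliberate simplification of density-based outlier detection used by
  full EEG pipelines; it targets the same 3-SD contract but is not
  numerically interchangeable with them.
* SMOTE neighbourhoods in 1-D make interpolation equivalent to jittering
  within the class range; with exactly 3 members per class the synthetic
  points are confined to the two gaps between them.
* The two-stage average-then-t-test treats per-participant slope estimates
  as exchangeable observations; no random-effects weighting by
  per-participant precision is attempted.
* One-sided inference is hard-wired to the directional hypothesis
  (positive coupling); users testing the opposite direction must negate
  the feature.
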