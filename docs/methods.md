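# Methods

## Scope and data model

`bioqc` evaluates the quality of single-channel biopotential recordings
(ECG, EMG, EEG) and compares a test channel against a simultaneously
recorded reference channel. All traces are uniformly sampled microvolt
series (nominal 1000 Hz); sample *i* lives at `t0 + i/fs` (0-based) and all
intervals are half-open `[t_start, t_end)` so that sliced spectra never
double-count boundary samples. The canonical on-disk format is delimited
text (`time_s,value_uV` or a single value column); two-column files are
validated against 1% timing jitter.

## Preprocessing

Band-pass filters are 4th-order Butterworth applied forward–backward
(zero-phase), per modality: 0.3–100 Hz (ECG), 10–2000 Hz (EMG),
0.3–50 Hz (EEG), plus a 60 Hz IIR notch (Q = 30) everywhere. A requested
upper edge above 0.45·fs is clipped there with a logged warning — at
fs = 1000 Hz the EMG band effectively becomes 10–450 Hz, since content
above Nyquist does not exist in the sampled record. Zero-phase filtering
was chosen because the delineator and all HRV timing metrics depend on
undistorted wave positions; a causal filter would bias every fiducial
point by its group delay.

## QRS detection and delineation

R peaks come from the two-moving-average, knowledge-based detector:
band-pass 8–20 Hz, squaring, an event-scale moving average (W1 = 97 ms)
compared against a beat-scale moving average (W2 = 611 ms) plus an offset
of 0.08 × mean squared energy; contiguous blocks wider than W1 each yield
one peak (argmax of squared energy, earliest sample on ties), with a
250 ms refractory rule keeping the stronger of close pairs. All thresholds
are relative, so detection is invariant to amplitude scaling.

Delineation is a deterministic windowed extremum search relative to each
R peak — Q = min on [−60, −8] ms, S = min on [+8, +60] ms, P = max on
[−250, −80] ms, T = max on [+80, +400] ms with the T window truncated at
55% of the current NN interval. Windows falling off the record mark the
wave absent. This is a transparent stand-in for heavier delineation
toolkits; equivalence with any specific toolkit is not claimed, and the
windows are configuration-exposed.

## ECG signal-quality indices

* **kSQI** is Pearson (non-excess) kurtosis, so the "> 5 is excellent"
  rule sits meaningfully above the Gaussian value of 3. An excess-form
  flag exists for sensitivity analyses.
* **pSQI** and **basSQI** are band-power ratios on Welch periodograms
  (Hann, 50% overlap, density scaling, trapezoidal band integration with
  interpolated edges so adjacent bands tile exactly). pSQI uses
  2048-sample segments (~0.49 Hz resolution); basSQI uses 8192-sample
  segments (~0.12 Hz) because it splits the spectrum at 1 Hz and the
  coarser grid would leak sub-Hz energy across the band edge.
* kSQI and pSQI are computed on the band-passed + notched trace; basSQI
  on a notch-only copy, because the 0.3 Hz high-pass edge of the ECG band
  would remove exactly the sub-1 Hz content basSQI measures. The mean
  (0 Hz) is removed before spectral estimation — electrode offset is not
  baseline wander.

## Fuzzy comprehensive evaluation

Membership functions map each SQI to three quality levels
(1 = excellent, 2 = barely acceptable, 3 = unacceptable); the fuzzy vector
is the bounded weighted sum `s_j = min(1, Σ_i w_i r_ij)` with weights
(0.4, 0.4, 0.2) for (kSQI, pSQI, basSQI), and the score is
`v = Σ s_j²·j / Σ s_j²`, graded E (v ≤ 1.50) / B (1.50 < v < 2.40) /
U (v ≥ 2.40) with closed boundaries exactly as printed.

The default membership set was calibrated under three constraints:

1. the three reference triplets — (7.33, 0.67, 0.99), (9.55, 0.71, 0.99),
   (8.85, 0.70, 0.99), reported for a wet electrode, a dry nanowire
   electrode, and the same dry electrode at 50% strain — must reproduce
   their common published score 1.17 (± 0.02);
2. improving any single SQI toward its excellent region, the others held
   fixed, must never increase v (verified on dense grids and
   property-tested);
3. memberships lie in [0, 1] and no level is empty on the attainable range.

Design features that realise these constraints:

* All kSQI memberships are evaluated on the clipped statistic min(k, 5):
  beyond the excellence threshold, extra kurtosis conveys no additional
  quality information. This is what makes three records with distinct
  kSQI (7.33–9.55) share a single score, and it is the natural reading of
  a published table in which they do.
* The pSQI level-2 rectangle [0.4, 0.9] deliberately contains the level-1
  window [0.5, 0.8]: an in-window power ratio retains a residual
  "barely acceptable" membership. This residual, together with its
  basSQI analogue, is what lifts the perfect-record score from 1.0 to the
  printed 1.17.
* Level-2 memberships are *subnormal* (heights 0.3 for kSQI, 0.14 for
  basSQI). A full-height mid-scale bump would violate constraint 2: the
  squared aggregation lets a large `s₂` pull v upward even while level-3
  mass drains away. The basSQI level-2 trapezoid has no rising edge (it
  is a plateau below 0.90) for the same reason, and its falling edge ends
  at a knot beyond 1.0 (calibrated value 1.049687,
  `calibrate_bassqi_residual_knot` reproduces it by grid search) so that
  a residual membership persists up to a perfect statistic and the edge
  stays gentle enough for the level-1 rise to dominate.
* The basSQI level-1 edge rises over [0.90, 1.0] without an interior
  saturation point; saturating earlier would leave a sub-range where only
  the level-2 membership changes, which again breaks monotonicity.

With these defaults a triplet whose pSQI lies inside [0.5, 0.8] cannot
reach grade U (its guaranteed level-1/2 mass bounds v below 2.4) — an
intentional property: a record with healthy QRS-band power is at worst
"barely acceptable" pending reassessment.

**Decision workflow.** E → accept. U → re-record when pSQI is outside
[0.5, 0.8] (a QRS power deficit cannot be filtered away; this route
dominates when several SQIs fail), otherwise denoise and re-evaluate.
B → reassess once; a B persisting on the rerun is dispatched by the U
rules.

## HRV

NN intervals are successive R-peak differences with ectopy/outlier
rejection (outside 300–2000 ms, or deviating > 30% from the running
median of five; rejected counts are logged). Population (1/n) variance
denominators are used throughout so that SD1 = SDSD/√2 holds exactly.

One deliberate naming split: `sdnn_printed` is the standard deviation of
the *successive differences* — the definition used verbatim by the
protocol this package implements, which the broader HRV literature calls
SDSD — while `sdnn_conventional` is the standard deviation of the NN
intervals themselves. Reports carry both.

Frequency-domain analysis resamples the NN series to a uniform 4 Hz grid
by cubic spline against beat times (standard HRV practice; the rate is
configuration-exposed), removes the mean, and integrates a Welch spectrum
(Hann, 256-sample segments ≈ 64 s, 50% overlap) over VLF [0, 0.04),
LF [0.04, 0.15), HF [0.15, 0.4) and VHF [0.4, 2) Hz. Band powers tile
exactly to the total by construction. The "average NN-FFT amplitude"
curve averages one-sided Hann-windowed FFT magnitudes bin-wise over the
same segmentation. The random-slice comparison draws seeded disjoint
windows (rejection sampling, capped at 10⁴ attempts; defaults 10 × 60 s,
scaled down in the bundled demo so the windows always fit), computes
time-domain HRV per channel per window, and correlates each parameter
across windows (mean-centred cross-correlation; identical inputs define
ρ = 1 even for degenerate constant parameters).

## EEG

The spectrogram is a Hann STFT (2 s windows, 50% overlap → 0.5 Hz
resolution, ample for the 8–13 Hz alpha band). The PSD is the classical
periodogram |X(f)|²/N, one-sided; by default a Hann window with power
compensation controls leakage, and a `raw=True` flag restores the literal
rectangular-window form. A Parseval check (integral ≈ variance within 5%)
is part of the test suite.

Alpha presence per epoch: per-Hz alpha-band power is compared against the
mean per-Hz power of two flank bands, 4–7 Hz and 14–17 Hz, chosen to avoid
both the sub-4 Hz ocular artifact range and the mains region; alpha is
declared present when the ratio reaches 2.0. The ratio is scale-invariant
and the threshold is configuration-exposed; the protocol's own statement
is qualitative ("significant" band energy), so tests anchor the verdicts
to synthetic ground truth rather than to the threshold's absolute value.
The reported amplitude range is the 5th–95th percentile of the 8–13 Hz
analytic (Hilbert) envelope, doubled to read as peak-to-peak microvolts,
matching how clinical alpha amplitudes (5–20 µV) are quoted.

## SNR and cross-correlation

SNR uses demeaned RMS of a designated signal epoch and a designated noise
epoch: the protocol never operationalises the noise measurement for real
recordings, so the contract here is explicit — a caller-designated
`noise_epoch` annotation for real data, and the exact injected noise
trace for synthetic data, with the provenance recorded in reports.

The cross-correlation coefficient is implemented literally (no mean
removal, no lag search). It can be negative for anti-correlated inputs;
the value is reported as-is rather than clamped. A `centered=True`
variant exists because correlating averaged spectra or HRV parameter
vectors conventionally removes the mean first; every report states which
variant produced each number.

## Synthetic data

The generators emulate the statistical structure the analysis assumes,
with ground truth sufficient to compute an independent oracle for every
downstream metric:

* **NN process** — mean NN 800 ms (75 bpm resting adult) plus sinusoidal
  LF (0.1 Hz, 30 ms) and HF (0.25 Hz, 20 ms) modulation and 5 ms white
  jitter; any NN ≤ 250 ms aborts as non-physiologic.
* **ECG** — five Gaussian kernels per beat; defaults (µV, s):
  P(150, −0.20, 0.025), Q(−100, −0.025, 0.010), R(1000, 0, 0.012),
  S(−150, +0.025, 0.010), T(300, +0.30, 0.060). A kernel sum is
  analytically transparent (R times equal beat times exactly) and
  suffices to exercise detection, delineation, the SQIs (clean output
  lands at kSQI > 5 and pSQI ≈ 0.73) and HRV; no dynamical-system realism
  is attempted.
* **EMG** — 20–450 Hz band-limited noise, epoch RMS = 50·force_level µV,
  ~1 µV quiescent baseline.
* **EEG** — 1/f background (0.5–45 Hz, 5 µV RMS); eyes-closed epochs add
  an amplitude-modulated 10 Hz alpha component whose peak-to-peak
  envelope sweeps 10–16 µV at 0.4 Hz — inside the clinically typical
  5–20 µV band with margin on both sides, so that the *measured* envelope
  (which includes in-band background) also stays inside that band;
  eyes-open-moving epochs add large slow (< 4 Hz) ocular transients.
* **Noise injection** — baseline wander (0.3 Hz, 5 µV) + powerline
  (60 Hz, 5 µV) + white noise. When a target SNR is requested, the white
  component alone is rescaled by solving the quadratic
  ‖fixed + α·white‖² = N·RMS_target² exactly, preserving the structured
  artifact content while achieving the target to machine precision; a
  structured floor louder than the budget is an error.

What the generators do **not** emulate: electrode–skin interface physics,
impedance, motion-artifact morphology beyond slow transients, arrhythmias
or ectopy, multi-channel correlation structure beyond shared ground truth,
and real EEG nonstationarity. Passing tests therefore demonstrate the
correctness of the *analysis* under the stated signal model, not
performance claims about any physical electrode.

## Numerical conventions

Trapezoidal band integrals interpolate the curve at band edges, making
adjacent bands tile exactly. Argmax ties resolve to the earliest sample.
Empty delineation windows mark waves absent instead of erroring. All
random draws flow through `numpy.random.default_rng` with explicit seeds;
every pipeline echoes its configuration, seed and a config hash into the
report header so any number is reproducible from the report alone.

## Problem sizes

Bundled tests and the demonstration pipeline run on records of 1–5
minutes at 1000 Hz, 300-beat NN series, and 2¹⁶–2¹⁷-sample noise
fixtures — sizes at which every spectral estimate in the package is
well-converged while the whole suite executes in seconds.

## Known limitations

* The delineator is windowed-extremum based; biphasic or inverted waves
  outside the default windows will be mislabelled.
* The fuzzy membership parameters are calibrated to one published worked
  example plus structural constraints; they are this package's defaults,
  not a reproduction of any third party's unpublished parameter set.
* `hrv_freq` requires ≥ 120 s records; spectral SQIs require ≥ 10 s.
* The cross-correlation is zero-lag only; channels are assumed to share
  an acquisition clock.
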