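# Methods

## Signal model and preprocessing

All channels are linearly interpolated onto the integer-second grid of their
common support (no extrapolation; the frame is the intersection of channel
spans). Breath-by-breath V̇O₂ is treated as sampled at breath-end times; the
timestamp convention is irrelevant after interpolation at the time scales
involved (breaths every ~3 s against dynamics slower than 100 s).

ΔHR is the 1-s lagged difference of heart rate with the first element set to
zero — dropping it instead would misalign every channel by one sample.

The model low-pass is a 4th-order Butterworth at 0.01 Hz applied
forward-backward (`sosfiltfilt`), i.e. zero phase and −6 dB at cutoff
squared to −12 dB. Zero phase matters: a causal filter would delay the
filtered V̇O₂ target relative to its drivers and bias the temporal dynamics
the gain analysis measures. Edge transients are handled with 300 samples of
odd-reflection padding per end (about three characteristic periods of the
cutoff), capped for short inputs. Training pairs the filtered features with
the *filtered* V̇O₂ target; validation always uses the raw measured V̇O₂ as
reference.

Feature order is fixed: HR, ΔHR, V̇E, BF, H_acc, CAD.

## PRTS protocol

The cadence schedule is a maximal-length ternary m-sequence from a GF(3)
linear-feedback shift register. Default generator: degree 3, polynomial
x³ + 2x + 1, initial state (0, 0, 1) — primitivity is enforced at run time
by measuring the period against 3^m − 1, and defaults for degrees 2/4/5 are
included. Any primitive degree-3 polynomial yields a shifted/decimated
equivalent sequence, so the choice is recorded in configuration for
reproducibility rather than being scientifically material.

Field symbols map antisymmetrically ({0→0, 1→+1, 2→−1}) onto cadence levels
base ± delta (default 105 ± 30 steps·min⁻¹, 30-s steps). This makes the
centred cadence antiperiodic, c(t + T/2) = −c(t), so even harmonics vanish
*exactly* (measured < 1e−15 relative), which is why only odd harmonics are
analysed. The 300-s warm-up prepends the last ten symbols of the sequence so
the analysed window starts in sequence steady state; the two PRTS repeats
use identical phase (required for point-wise averaging). Harmonics retained:
odd k with k/T ≤ 0.008 Hz — {1, 3, 5} for the 780-s period — because V̇O₂
above that band is confounded by circulatory non-linearities.

## Regression forest

Written from first principles and stored as flat arrays for vectorised
prediction. Node splitting minimises the sum of squared residuals over a
random ⌈p/3⌉-subset of features (2 of 6) and all midpoints between
consecutive distinct sorted values, restricted to splits leaving at least
`min_leaf` samples per child; prefix-sum evaluation with node-centred
targets keeps the computation O(n log n) per node and well conditioned.

Numerical tie policy: distinct features can induce the same row bipartition
and therefore mathematically equal SSRs; comparisons use a relative
tolerance (1e−10 of the node sum of squares) and resolve ties to the lowest
feature index, then the smallest threshold — deterministic regardless of
rounding.

Defaults where the method leaves freedom: 100 trees, `min_leaf` 5, bootstrap
of size n with replacement, uniform tree weights (the weight vector is kept
in the data model so non-uniform weighting remains expressible). Randomness
derives from one root seed fanned out through `SeedSequence` substreams per
tree and per fold, so results are reproducible independent of evaluation
order. Cross-validation is leave-one-participant-out: one forest per
held-out participant (16 for the default cohort), each trained on all
annotated segments of the remaining participants; the fold forest provides
that participant's out-of-sample predictions, and the unweighted mean of all
fold forests is the final deployable predictor.

Reported cohort runs (tests and the acceptance script) use 20 trees,
`min_leaf` 20 and every-2nd-second training rows: 1-Hz physiological series
are strongly autocorrelated, so this thinning costs ≈ nothing in accuracy
(held-out r ≈ 0.99 against the filtered target) while keeping a full
16-participant study under a minute.

## Gain analysis and MNG

The two PRTS repeats (one 780-s period each, aligned by protocol
annotation) are averaged point-wise; an optional ±5-s cross-correlation
alignment exists but is off by default since the simulator and annotation
are exact. Spectra are computed from exactly one period with mean removal
and *no window*: the stimulus is periodic and N = period × rate, so every
harmonic sits exactly on a DFT bin and windowing would only bias amplitudes.
Gains are amplitude ratios |Y_k|/|X_k| (the natural reading of
"output/input ratio"); the input is the unfiltered averaged H_acc — at
≤ 0.0064 Hz a 0.01-Hz low-pass applied to both series would cancel in the
ratio anyway. Requesting a harmonic whose input amplitude is below 1e−12 of
the input maximum (e.g. any even harmonic) is an error, not a zero.

MNG = 100 × mean of normalised gains. The first harmonic (normalised gain
identically 1) is *included* by default — "mean of the normalised gains"
does not exclude it, and including it bounds noise-free first-order MNG in
(51.11, 100] for harmonics {1, 3, 5}; the `include_first=False` convention
is exposed because the alternative is defensible. The closed-form oracle is
MNG(τ) = 100 × mean_k √((1 + (2πf₁τ)²)/(1 + (2πf_kτ)²)), strictly
decreasing in τ.

## METS analysis

1 MET = 3.5 ml·min⁻¹·kg⁻¹ (the universal convention; configurable). Bands
are half-open — rest < 2, light [2, 4), moderate [4, 6), excluded ≥ 6 — so
boundary values assign deterministically (3.9 → light, 4.0 → moderate).
Banding follows the *measured* intensity; predicted means per band quantify
the predictor's ability to separate metabolic demands. Resting metabolic
rate is the mean of the last 60 s of the rest segment (the most settled
portion; the window placement within the segment is a package choice).

## Synthetic cohort

What it emulates: cadence-driven first-order V̇O₂ and HR kinetics
(dv/dt = (target(u) − v)/τ, discretised by the exact exponential-hold update
v[t+1] = a·v[t] + (1 − a)·target[t], a = e^(−1/τ) — exact for piecewise-
constant drive, no Euler error); ventilation coupled proportionally and
breathing frequency affinely to noise-free V̇O₂; hip acceleration affine in
cadence; breath-by-breath V̇O₂ sampling at exponential inter-breath
intervals (mean 3 s) re-synchronised through the standard preprocessing
path; independent Gaussian noise per channel.

Defaults define the study conditions: 16 participants; τ_V̇O₂ ~ U(20, 60) s;
resting V̇O₂ ~ U(3.2, 4.2) ml·min⁻¹·kg⁻¹; static gain
U(0.095, 0.115) ml·min⁻¹·kg⁻¹ per steps·min⁻¹, which keeps PRTS peaks below
6 METS; HR kinetics ~25 % faster than V̇O₂; noise SDs 0.5 (V̇O₂,
breath-scatter calibrated so that two-repeat averaging over three harmonics
resolves the τ range — see below), 2 bpm (HR), 1.5 (V̇E), 1.5 (BF), 0.05 g
(H_acc), 2 steps·min⁻¹ (CAD). The protocol is rest (180 s), warm-up + PRTS1,
a 19-min activities-of-daily-living script (sitting, shelf organisation,
carrying, stairs, self-paced walking, computer work as cadence levels),
warm-up + PRTS2.

The V̇O₂ noise SD deserves a note: the harmonic amplitudes at k = 5 are
~0.5 ml·min⁻¹·kg⁻¹ for slow participants, and the per-bin noise amplitude
after repeat averaging is ~6 % of that at SD 0.5. At substantially larger
breath scatter the per-participant MNG jitter (± ≈ 3 points) exceeds the MNG
spacing of neighbouring time constants and rank recovery degrades; 0.5 is a
clean-cart operating point at which the protocol's own averaging design
functions as intended.

What it does **not** emulate — and therefore what passing tests do not show
about real data: V̇O₂ slow-component and drift, nonlinear kinetics above
moderate intensity, cardiovascular drift, raw 64-Hz accelerometry or
activity-specific H_acc signatures (stairs vs level walking at equal
cadence), sensor dropout, and any deviation from exact first-order
behaviour. Real-cohort accuracies will be lower; the synthetic cohort
verifies the *machinery* (protocol arithmetic, filtering, splitting,
cross-validation plumbing, spectral estimation, statistics), plus
end-to-end parameter recovery under its own generative assumptions.

## Statistics

Bias is mean(measured − predicted); limits of agreement are
bias ± 1.96·SD(d) with the n−1 sample SD, and the same 1.96·SD half-width is
reported as the confidence interval around the bias. Identical series make
the bias t-test degenerate; this is flagged rather than raised. Group-level
agreement is reported both pooled (all samples concatenated) and as
per-participant tables, since the two summaries answer different questions.
Correlation p-values ignore the autocorrelation of 1-Hz series and are
reported for completeness, not inference. With fewer than three
participants the cohort-level MNG agreement reports only the bias (flagged
degenerate).

## Known limitations

- MNG estimates use amplitude ratios without coherence weighting; very low
  signal-to-noise at k = 5 inflates gains slightly (|S + N| ≥ |S| in
  expectation).
- The 300-s warm-up equals 5τ only for the fastest defaults; for τ = 60 s a
  residual transient biases measured MNG by ≈ 0.25 points.
- The forest cannot extrapolate beyond the convex hull of training targets;
  participants with resting or peak V̇O₂ outside the training cohort's range
  are clamped toward it.
- Config-driven protocol variants (different degrees/step durations) are
  supported by construction but only the 780-s default is exercised by the
  full acceptance-level pipeline.
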