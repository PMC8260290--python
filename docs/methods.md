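# Methods

This note documents the models, numerical choices, and limitations behind
`healthgrid`, stage by stage in pipeline order.

## Oscillometric blood-pressure estimation

### Model

The oscillometric principle: as a cuff deflates past the arterial pressure
range, small pressure oscillations appear whose amplitude peaks near mean
arterial pressure. We model the amplitude envelope versus cuff pressure as
a Gaussian `y = y_max·exp(−(x − x_max)²/s)` with width parameter `s`
(mmHg²), and fit it in log space, where the model is a quadratic
`ln y = b0 + b1·x + b2·x²` solved by ordinary (unweighted) least squares.
The mapping back is algebraically exact: `s = −1/b2`, `x_max = b1·s/2`,
`y_max = exp(b0 + x_max²/s)`. A fit with `b2 ≥ 0` (log envelope not
concave) or a rank-deficient design matrix raises `FitInvalidError` rather
than returning a junk envelope.

Systolic and diastolic pressures are the cuff pressures where the fitted
envelope crosses `Ks·y_max` above the peak and `Kd·y_max` below it. The
defaults `Ks = 0.48`, `Kd = 0.58` are the coefficients in common clinical
use; values in roughly 0.46–0.64 and 0.43–0.73 are admissible, and both
are parameters of `AmplitudeCoefficients`. Whether the systolic crossing is
taken on the high-pressure side and diastolic on the low side is a
convention; we fix SP above the peak, DP below, which matches the clinical
reading of the deflation curve.

### Signal processing

The filters and the pulse detector are not prescribed by the estimation
principle; the choices here are standard practice and any zero-phase design
meeting the same contracts would do:

- **Separation.** Zero-phase (forward–backward) Butterworth filters:
  low-pass at 0.5 Hz for the static deflation ramp, band-pass 0.5–8 Hz for
  the oscillations (pulse rates 30–200 bpm are 0.5–3.3 Hz; the upper edge
  leaves room for harmonics). Recordings must be ≥ 5 s and sampled at
  ≥ 16 Hz (twice the band-pass upper cutoff).
- **Pulse rate.** Welch-PSD peak in the 0.5–3.3 Hz band, refined by the
  median inter-peak interval after a narrow band-pass (0.6–1.6× the
  spectral estimate). The spectral first guess is robust to broadband
  noise, where naive peak counting is not.
- **Amplitude measurement.** Per-pulse peak-to-trough amplitude is
  estimated by synchronous demodulation: the oscillation signal is mixed
  down at the pulse rate and low-passed at 0.3 Hz, so each amplitude
  averages several beats of data instead of reading one noisy extremum.
  The noise scale is measured by demodulating at 1.5× the pulse rate — a
  band between the fundamental and its first harmonic that contains no
  pulse energy — calibrated via the Rayleigh-magnitude median, and the
  measured amplitudes are Rice-bias corrected in quadrature.
- **Point selection.** Pulses weaker than 5 % of the strongest, or than 3
  standard deviations of the measured noise, are excluded, as are pulses
  within 5 s of either end of the recording (zero-phase filter
  transients). The unweighted log-space fit is very sensitive to
  near-noise-floor tail amplitudes, whose logarithms have unbounded error;
  the 3σ rule removes exactly those points and reduces to the plain 5 %
  rule on clean signals.

### Cuff simulator

`simulate_recording` produces a linear deflation from SP + 50 mmHg down to
DP − 55 mmHg (clamped positive) at 3 mmHg/s, sampled at 100 Hz, with a
cosine pulse train whose peak-to-trough amplitude follows a Gaussian
envelope of peak 3 mmHg — a typical cuff oscillation amplitude — plus
optional white Gaussian sensor noise. The deflation overshoot on both ends
keeps every detectable pulse clear of the extractor's edge margins. By
default the envelope's peak position and width are solved from the two
threshold equations so that the default-coefficient reverse lookup returns
the requested pressures exactly in the noiseless case; the peak divides
[DP, SP] in the ratio √ln(1/Ks) : √ln(1/Kd). If an explicit width
`envelope_s` is supplied, the peak is placed from the systolic equation
alone and only SP round-trips exactly — the two-threshold system is
overdetermined once the width is pinned.

The simulator emulates amplitude physiology only: a clean linear deflation,
a strictly periodic pulse at constant rate, a symmetric Gaussian envelope,
and white sensor noise. Real cuff data have motion artifacts, asymmetric
envelopes, respiration-modulated amplitudes, and rate variability; passing
round-trip tests here demonstrates correctness of the estimation chain, not
clinical accuracy.

## Feature expansion and standardization

Blood-pressure sessions expand exactly as APP = SP − DP,
MAP = DP + (SP − DP)/3, ARPP = HR·SP. Pedometer step events expand with
explicit conventions (the protocol names the six outputs but not the
thresholds): stride 0.0007 km/step, fast motion = clock minutes with
≥ 100 steps, sleep = total step-free gaps of ≥ 20 min intersected with a
21:00–09:00 night window, awake = 24 h − sleep. All four are keyword
parameters of `expand_activity`.

Standardization maps each index's range (15 indices: weight 0–150 kg,
fat 0–50 %, SP/DP 0–250 mmHg, HR 0–200 bpm, APP 0–200, MAP 0–300,
ARPP 0–50000, steps 0–30000, distances 0–20 km, durations 0–24 h,
temperature 30–45 °C) linearly onto gray 0–255, rounding half-up.
Out-of-range measurements are clamped rather than rejected — wearable
spikes should saturate, matching the bounded gray scale — and
`destandardize` inverts the map exactly on the 0–255 lattice.

## Health map

The 6×6 layout is fixed: row 1 and 2 carry the two sessions'
(SP, DP, HR, APP, MAP, ARPP); row 3 weight and fat; row 4 the activity
six-tuple; rows 5 and 6 the two temperatures, first cell each. The 14
cells the layout leaves unassigned are zero-filled — a deterministic
choice, visually neutral as "lowest gray". `build_map` is a pure function;
maps serialize losslessly as binary PGM (P5), with 8-bit grayscale PNG
accepted for interchange.

## Classifier

The network topology is fixed (it is the method, not a tuning surface):
conv 3@2×2 → conv 9@2×2 → max-pool 2×2 → fully connected → softmax(3),
same-padding, stride 1, so the pooled feature map flattens to 9·3·3 = 81
units. The pooling stage sits after both convolutions. Free
hyper-parameters live in `CNNConfig` with defaults: ReLU activation (tanh
available), 32 hidden units, cross-entropy loss, Adam at 10⁻³, 30 epochs,
batch 32, He-normal initialization. Inputs are gray/255 ∈ [0, 1].

The implementation is plain numpy with explicit backpropagation — at 6×6
inputs and ~2,900 parameters this trains in seconds on one CPU and, with a
single seeded generator for initialization and shuffling, is
bit-reproducible end to end. Checkpoints (`.npz` weights + config)
round-trip predictions bit-exactly. Max-pool gradient ties are shared
equally between tied cells, keeping backprop deterministic.

## Evaluation

Three-class results are scored one-vs-rest per class (pool the other two
classes as negatives), giving the four binary rates; the macro summary is
the unweighted mean and population sd of the three per-class accuracies.
Micro accuracy (trace/total) is exposed separately and never conflated
with the macro mean. Degenerate divisions (no predicted positives / no
true positives) report 0 with an explicit flag instead of NaN, and F1 is 0
whenever TP = 0. Relative measurement error is
`100·|measured − reference|/reference`, rounded half-up to one decimal;
the bundled cuff and pedometer verification tables are fixed
reference/test pairs against which this arithmetic is checked cell by
cell.

## Synthetic data

Each health state has a `ClassProfile` of per-measurement means and sds.
Defaults follow a plausible vitals gradient — health ≈ 115/75 mmHg, 70 bpm,
36.6 °C and high activity; sub-health ≈ 135/88, 82 bpm, 37.1 °C; illness ≈
155/98, 95 bpm, 38.2 °C and low activity; spreads ≈ 8 mmHg and 0.3 °C.
These are generator parameters, not clinical claims. Draws are truncated
normals bounded by the standardization ranges (so clamping is rarely
active), and SP is built as DP plus a positive pulse-pressure gap, making
SP > DP structural. Datasets contain exactly `n_per_class` maps per class
with a per-class (stratified) 80/20 split, preserving the ⅓ balance in
both partitions; everything is deterministic per seed.

`scale_separation` interpolates all class means *and spreads* toward their
common average: scale 1 is the default separable regime (mean inter-class
distance on the blood-pressure cells ≥ 60 gray levels, where the CNN
reaches ≥ 95 % test accuracy), scale 0 collapses the three classes onto
one distribution, on which any classifier sits at chance (⅓). Records are
drawn independently day to day; longitudinal structure (drift, weekly
rhythms) is not emulated, so results say nothing about time-series
generalization.

## Problem sizes

The test suite and the acceptance script use: 300-map datasets (100 per
class) for classifier training checks and a 900-map collapsed-profile
control; the full 3,000-map protocol dataset for the dataset-shape check
and the headline CNN accuracy; 100 simulated recordings for the noisy
round-trip error and a 21-point pressure grid for the noiseless one. The
numpy CNN trains on the 2,400-map split in a few seconds, so these sizes
are comfortable on a single CPU.

## Known limitations

- The Gaussian-envelope model is symmetric; real envelopes are often
  right-skewed, which biases the width-based systolic/diastolic lookup.
- Unweighted log-space fitting remains noise-sensitive near the envelope
  tails even after 3σ point selection; amplitude-domain or weighted
  fitting would be more efficient statistically but is out of scope here.
- The classifier's reported accuracies are on synthetic, independently
  drawn records; they demonstrate the pipeline's learnability properties,
  not expected performance on clinician-labeled wearable data.
- `expand_activity` works from step-event timestamps only; it does not
  process raw accelerometry.
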