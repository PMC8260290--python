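# healthgrid

A tested Python implementation of a wearable smart-health pipeline:
oscillometric blood-pressure estimation, encoding of a day's vitals into a
6×6 grayscale "health map" image, and a small convolutional network that
classifies each map as **health**, **sub-health**, or **illness**. Synthetic
generators stand in for the cuff hardware and for clinician-annotated
records, so every stage is runnable and testable without any device or
private data. It is aimed at people prototyping physiological-signal
processing or feature-to-image classification pipelines.

## The methods

**Oscillometric blood pressure.** A deflating cuff's pressure signal is
split by zero-phase filtering into a static ramp and the small arterial
oscillations riding on it. Each pulse contributes an envelope point
(xᵢ, yᵢ): cuff pressure at the pulse and the pulse's peak-to-trough
amplitude. The amplitude envelope is modeled as a Gaussian

```
y = y_max · exp(−(x − x_max)² / s)
```

and fitted by log-linearized least squares: ln y is a quadratic in x with
coefficients b₀ = ln y_max − x_max²/s, b₁ = 2·x_max/s, b₂ = −1/s, solved by
ordinary least squares B = (XᵀX)⁻¹XᵀZ on the (1, x, x²) design matrix.
Systolic and diastolic pressure are read off where the fitted envelope
falls to Ks·y_max above the peak and Kd·y_max below it (clinical defaults
Ks = 0.48, Kd = 0.58):

```
SP = x_max + √(s·ln(1/Ks)),   DP = x_max − √(s·ln(1/Kd))
```

**Health maps.** Daily measurements are expanded into derived indices —
pulse pressure APP = SP − DP, mean arterial pressure MAP = DP + (SP − DP)/3,
rate-pressure product ARPP = HR·SP, and a pedometer six-tuple — then each
index is standardized linearly onto gray values 0–255 over its measurement
range (weight 0–150 kg, temperature 30–45 °C, ARPP 0–50000, …) and placed
on a fixed 6×6 grid: two blood-pressure rows, weight/fat, activity, and two
temperature cells, with unassigned pixels zero.

**Classification.** A pared-down LeNet-5 — conv(3 filters, 2×2) →
conv(9 filters, 2×2) → 2×2 max-pool → fully connected → 3-way softmax —
is trained with Adam on cross-entropy. It is implemented directly in numpy
(explicit backpropagation), which keeps training bit-reproducible per seed.
Evaluation uses one-vs-rest accuracy/recall/precision/F1 per class and the
macro mean ± sd across the three classes.

## Worked example

Simulate a cuff deflation for a subject with true pressures 120/80 at
72 bpm, then estimate the pressures back from the raw signal:

```
$ healthgrid bp-simulate --sp 120 --dp 80 --hr 72 --seed 1 --out rec.csv
{
  "samples": 4834,
  "duration_s": 48.33,
  "out": "rec.csv"
}
$ healthgrid bp-estimate --input rec.csv
{
  "SP": 119.91,
  "DP": 80.09,
  "HR": 72.3,
  "x_max": 98.52,
  "s": 623.49,
  "n_pulses": 34
}
```

The estimator recovered 119.91/80.09 mmHg from a 48 s recording with 34
usable pulses; `x_max` (98.5 mmHg) is the envelope peak — the mean-arterial
point — and `s` its squared width. Other subcommands: `encode` builds a
health-map image from a daily record CSV, `simulate-dataset` writes a
labeled PGM dataset, `train` / `predict` / `evaluate` drive the CNN, and
`verify-tables` recomputes the device-verification error tables.

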