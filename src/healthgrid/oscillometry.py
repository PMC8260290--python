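"""Oscillometric blood-pressure estimation from cuff-deflation recordings.

The oscillometric method reads blood pressure off the small arterial
oscillations superimposed on a slowly deflating cuff. The composite sensor
signal is split by zero-phase filtering into a static deflation ramp and a
dynamic oscillation component; each detected pulse contributes one envelope
point (x_i, y_i) — the cuff static pressure at the pulse peak and the pulse's
peak-to-trough amplitude. The amplitude envelope rises to a maximum near mean
arterial pressure and falls again, and is modeled as a Gaussian

    y = y_max * exp(-(x - x_max)^2 / s),

fitted by log-linearized least squares: taking logarithms turns the model
into a quadratic z = b0 + b1*x + b2*x^2 with

    b0 = ln y_max - x_max^2 / s,   b1 = 2*x_max / s,   b2 = -1/s,

solved with the ordinary normal equations B = (X^T X)^-1 X^T Z on the
(1, x, x^2) design matrix. Systolic and diastolic pressure are then the
cuff pressures where the fitted envelope falls to Ks*y_max above the peak
and Kd*y_max below it (clinical defaults Ks = 0.48, Kd = 0.58):

    SP = x_max + sqrt(s * ln(1/Ks)),   DP = x_max - sqrt(s * ln(1/Kd)).

A cuff simulator generates synthetic deflation recordings whose envelope
geometry is constructed so that the default coefficients recover the
requested pressures exactly in the noiseless case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "CuffDeflationRecording",
    "PulseEnvelope",
    "GaussianEnvelopeFit",
    "AmplitudeCoefficients",
    "BloodPressureEstimate",
    "SimulationTruth",
    "DEFAULT_COEFFICIENTS",
    "separate_components",
    "extract_envelope",
    "fit_envelope",
    "estimate_pressures",
    "estimate_blood_pressure",
    "solve_envelope_geometry",
    "simulate_recording",
    "read_recording_csv",
    "write_recording_csv",
]

# Filter band for the oscillation component: pulse rates 30-200 bpm are
# 0.5-3.3 Hz; the upper cutoff leaves room for waveform harmonics.
STATIC_CUTOFF_HZ = 0.5
DYNAMIC_BAND_HZ = (0.5, 8.0)
MIN_DURATION_S = 5.0
# Pulse detection: peaks at least 60/HR_max apart, at least this fraction of
# the largest oscillation. The detector is a convention; the envelope
# post-conditions are what downstream code relies on.
MIN_PULSE_FRACTION = 0.05
HR_MAX_BPM = 200.0
HR_MIN_BPM = 30.0
# Amplitude demodulation: baseband low-pass cutoff and the edge span
# discarded to keep zero-phase filter transients out of the envelope.
BASEBAND_CUTOFF_HZ = 0.3
EDGE_MARGIN_S = 5.0


class EnvelopeTooSparseError(ValueError):
    """Fewer than three usable pulses were detected."""


class FitInvalidError(ValueError):
    """The log-envelope is not concave (b2 >= 0) or the solve is degenerate."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth parameters of a simulated recording (simulator metadata)."""

    sp: float
    dp: float
    hr: float
    x_max: float
    s: float
    y_max: float
    pulse_pressures: np.ndarray  # static pressure at each generated pulse peak

    def detectable_pulse_count(self, min_fraction: float = MIN_PULSE_FRACTION) -> int:
        """Pulses whose envelope amplitude clears the detection threshold."""
        amp = self.y_max * np.exp(-((self.pulse_pressures - self.x_max) ** 2) / self.s)
        return int(np.sum(amp >= min_fraction * amp.max()))


@dataclass(frozen=True)
class CuffDeflationRecording:
    """Raw composite cuff-pressure signal over a deflation."""

    time: np.ndarray         # s, strictly increasing
    pressure: np.ndarray     # mmHg, finite and positive
    sample_rate: float       # Hz
    truth: SimulationTruth | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        pressure = np.asarray(self.pressure, dtype=float)
        if time.shape != pressure.shape or time.ndim != 1:
            raise ValueError("time and pressure must be 1-D arrays of equal length")
        if time.size >= 2 and np.any(np.diff(time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(pressure)) or np.any(pressure <= 0):
            raise ValueError("pressure must be finite and positive")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "pressure", pressure)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if self.time.size else 0.0


@dataclass(frozen=True)
class PulseEnvelope:
    """Amplitude-envelope sample points, in deflation (decreasing-x) order."""

    points: tuple[tuple[float, float], ...]  # (x_i cuff pressure, y_i amplitude)

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise EnvelopeTooSparseError(
                f"envelope needs at least 3 points, got {len(self.points)}"
            )
        if any(y <= 0 for _, y in self.points):
            raise ValueError("all envelope amplitudes must be positive")

    @property
    def x(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def y(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class GaussianEnvelopeFit:
    """Fitted Gaussian envelope with its log-space regression coefficients."""

    y_max: float  # peak amplitude, mmHg
    x_max: float  # cuff pressure at the peak, mmHg
    s: float      # width parameter, mmHg^2
    b0: float
    b1: float
    b2: float

    def __post_init__(self) -> None:
        if self.s <= 0 or self.b2 >= 0:
            raise FitInvalidError(f"width must be positive (s={self.s}, b2={self.b2})")

    def amplitude(self, x) -> np.ndarray:
        """Fitted envelope amplitude at cuff pressure(s) x."""
        x = np.asarray(x, dtype=float)
        return self.y_max * np.exp(-((x - self.x_max) ** 2) / self.s)

    def log_sse(self, envelope: PulseEnvelope) -> float:
        """Sum of squared log-space residuals on an envelope."""
        resid = np.log(envelope.y) - (self.b0 + self.b1 * envelope.x + self.b2 * envelope.x**2)
        return float(np.sum(resid**2))


@dataclass(frozen=True)
class AmplitudeCoefficients:
    """Normalized amplitude coefficients for the reverse lookup.

    Clinical defaults Ks = 0.48 (systolic) and Kd = 0.58 (diastolic);
    admissible ranges roughly 0.46-0.64 and 0.43-0.73.
    """

    ks: float = 0.48
    kd: float = 0.58

    def __post_init__(self) -> None:
        if not (0.0 < self.ks < 1.0 and 0.0 < self.kd < 1.0):
            raise ValueError(f"coefficients must lie in (0, 1): Ks={self.ks}, Kd={self.kd}")


DEFAULT_COEFFICIENTS = AmplitudeCoefficients()


@dataclass(frozen=True)
class BloodPressureEstimate:
    sp: float             # mmHg
    dp: float             # mmHg
    peak_pressure: float  # envelope maximum position, mmHg
    hr: float             # bpm

    def __post_init__(self) -> None:
        if not self.dp < self.peak_pressure < self.sp:
            raise ValueError(
                f"expected DP < peak < SP, got {self.dp}, {self.peak_pressure}, {self.sp}"
            )
        if min(self.sp, self.dp, self.hr) <= 0:
            raise ValueError("estimates must be positive")


# ---------------------------------------------------------------------------
# Static / dynamic separation
# ---------------------------------------------------------------------------

def separate_components(recording: CuffDeflationRecording) -> tuple[np.ndarray, np.ndarray]:
    """Split the composite signal into static ramp and oscillation components.

    Zero-phase Butterworth filtering: low-pass below the pulse band for the
    deflation trend, band-pass over the pulse band (and harmonics) for the
    oscillations. Returns arrays the same length as the recording.
    """
    if recording.duration < MIN_DURATION_S:
        raise ValueError(f"recording too short: {recording.duration:.2f} s < {MIN_DURATION_S} s")
    fs = recording.sample_rate
    if fs < 2.0 * DYNAMIC_BAND_HZ[1]:
        raise ValueError(
            f"sample rate {fs} Hz below twice the band-pass upper cutoff "
            f"({DYNAMIC_BAND_HZ[1]} Hz)"
        )
    sos_lo = signal.butter(2, STATIC_CUTOFF_HZ, btype="lowpass", fs=fs, output="sos")
    sos_bp = signal.butter(2, DYNAMIC_BAND_HZ, btype="bandpass", fs=fs, output="sos")
    static = signal.sosfiltfilt(sos_lo, recording.pressure)
    dynamic = signal.sosfiltfilt(sos_bp, recording.pressure)
    return static, dynamic


# ---------------------------------------------------------------------------
# Pulse envelope extraction
# ---------------------------------------------------------------------------

def _pulse_rate_hz(dynamic: np.ndarray, sample_rate: float) -> float:
    """Fundamental pulse rate from the oscillation spectrum (Welch PSD peak)."""
    nperseg = min(dynamic.size, int(8 * sample_rate))
    freqs, psd = signal.welch(dynamic, fs=sample_rate, nperseg=nperseg)
    band = (freqs >= HR_MIN_BPM / 60.0) & (freqs <= HR_MAX_BPM / 60.0)
    if not band.any():
        raise EnvelopeTooSparseError("no spectral content in the pulse band")
    return float(freqs[band][np.argmax(psd[band])])


def _pulse_peaks(dynamic: np.ndarray, sample_rate: float, f0: float) -> tuple[np.ndarray, float]:
    """Pulse-peak sample indices and a refined pulse rate.

    Refilters narrowly around the spectral fundamental to suppress
    out-of-band noise before peak picking; the rate is refined from the
    median interval of the strong peaks when enough are available.
    """
    nyq = sample_rate / 2.0
    lo, hi = 0.6 * f0, min(1.6 * f0, 0.95 * nyq)
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")
    narrow = signal.sosfiltfilt(sos, dynamic)
    peaks, _ = signal.find_peaks(narrow, distance=max(1, int(0.7 * sample_rate / f0)))
    if peaks.size:
        peaks = peaks[narrow[peaks] >= MIN_PULSE_FRACTION * narrow[peaks].max()]
    strong = peaks[narrow[peaks] >= 0.5 * narrow[peaks].max()] if peaks.size else peaks
    f = sample_rate / float(np.median(np.diff(strong))) if strong.size >= 3 else f0
    return peaks, f


def extract_envelope(
    static: np.ndarray,
    dynamic: np.ndarray,
    sample_rate: float,
    *,
    min_fraction: float = MIN_PULSE_FRACTION,
) -> PulseEnvelope:
    """One envelope point per detected pulse of the oscillation signal.

    Pulse instants are local maxima of the narrowband-refiltered oscillation
    signal, at least 60/HR_max s apart. The peak-to-trough amplitude of each
    pulse is estimated by synchronous demodulation: the dynamic signal is
    mixed down at the pulse rate and low-pass filtered, so the amplitude at
    each pulse instant averages several beats of data instead of reading a
    single noisy extremum. The quiet-decile noise floor of the demodulated
    amplitude is subtracted in quadrature, and pulses weaker than
    ``min_fraction`` of the strongest — or than three times the noise floor
    — are discarded, as are pulses inside the filter-transient margins at
    either end of the recording.

    Each point's abscissa is the static cuff pressure at the pulse instant;
    points come back in deflation (decreasing-pressure) order with strictly
    positive amplitudes.
    """
    static = np.asarray(static, dtype=float)
    dynamic = np.asarray(dynamic, dtype=float)
    if static.shape != dynamic.shape or static.ndim != 1:
        raise ValueError("static and dynamic must be 1-D arrays of equal length")

    f0 = _pulse_rate_hz(dynamic, sample_rate)
    peaks, f = _pulse_peaks(dynamic, sample_rate, f0)
    if peaks.size < 3:
        raise EnvelopeTooSparseError(f"only {peaks.size} pulses detected, need >= 3")

    # Synchronous demodulation: complex baseband envelope at the pulse rate.
    t = np.arange(dynamic.size) / sample_rate
    sos_lp = signal.butter(
        2, BASEBAND_CUTOFF_HZ, btype="lowpass", fs=sample_rate, output="sos"
    )

    def demod(freq: float) -> np.ndarray:
        mixed = dynamic * np.exp(-2j * np.pi * freq * t)
        baseband = (
            signal.sosfiltfilt(sos_lp, mixed.real)
            + 1j * signal.sosfiltfilt(sos_lp, mixed.imag)
        )
        return 4.0 * np.abs(baseband)  # peak-to-trough scale

    amp = demod(f)

    margin = int(EDGE_MARGIN_S * sample_rate)
    lo_i, hi_i = margin, amp.size - margin
    if hi_i - lo_i < 3:
        raise EnvelopeTooSparseError("recording too short after edge trimming")
    # Noise scale from an off-frequency demodulation at 1.5x the pulse rate:
    # that band lies between the fundamental and its first harmonic, so its
    # demodulated magnitude is pure noise. The Rayleigh magnitude median is
    # sigma*sqrt(2 ln 2), which calibrates sigma on the amplitude scale.
    noise_amp = demod(1.5 * f)
    noise_scale = float(np.median(noise_amp[lo_i:hi_i])) / 1.1774
    # Rice bias correction: E[M^2] = A^2 + 2 sigma^2.
    amp = np.sqrt(np.maximum(amp**2 - 2.0 * noise_scale**2, 0.0))

    candidates = [
        (float(static[pk]), float(amp[pk]))
        for pk in peaks
        if lo_i <= pk < hi_i and amp[pk] > 0
    ]
    if not candidates:
        raise EnvelopeTooSparseError("no usable pulses inside the trimmed recording")
    max_amp = max(y for _, y in candidates)
    threshold = max(min_fraction * max_amp, 3.0 * noise_scale)
    points = [(x, y) for x, y in candidates if y >= threshold]
    if len(points) < 3:
        raise EnvelopeTooSparseError(
            f"only {len(points)} pulses above threshold, need >= 3"
        )

    points.sort(key=lambda p: -p[0])
    return PulseEnvelope(points=tuple(points))


def estimate_heart_rate(dynamic: np.ndarray, sample_rate: float) -> float:
    """Heart rate (bpm) from the refined pulse rate of the oscillation signal."""
    dynamic = np.asarray(dynamic, dtype=float)
    f0 = _pulse_rate_hz(dynamic, sample_rate)
    peaks, f = _pulse_peaks(dynamic, sample_rate, f0)
    if peaks.size < 2:
        raise EnvelopeTooSparseError("need at least 2 pulses to estimate heart rate")
    return 60.0 * f


# ---------------------------------------------------------------------------
# Log-linearized Gaussian fit
# ---------------------------------------------------------------------------

def fit_envelope(envelope: PulseEnvelope) -> GaussianEnvelopeFit:
    """Fit the Gaussian amplitude model by least squares in log space.

    Minimizes sum_i (ln y_i - (b0 + b1 x_i + b2 x_i^2))^2 over the quadratic
    coefficients, then maps back: s = -1/b2, x_max = b1*s/2,
    y_max = exp(b0 + x_max^2/s). Raises :class:`FitInvalidError` when the
    design matrix is degenerate or the log envelope is not concave.
    """
    x = envelope.x
    z = np.log(envelope.y)
    if np.ptp(x) == 0:
        raise FitInvalidError("all envelope pressures identical; cannot fit")
    design = np.column_stack([np.ones_like(x), x, x**2])
    coeffs, _, rank, _ = np.linalg.lstsq(design, z, rcond=None)
    if rank < 3:
        raise FitInvalidError("singular design matrix (collinear envelope abscissae)")
    b0, b1, b2 = (float(c) for c in coeffs)
    if b2 >= 0:
        raise FitInvalidError(f"log envelope not concave (b2={b2:.3g} >= 0)")
    s = -1.0 / b2
    x_max = b1 * s / 2.0
    y_max = math.exp(b0 + x_max**2 / s)
    return GaussianEnvelopeFit(y_max=y_max, x_max=x_max, s=s, b0=b0, b1=b1, b2=b2)


# ---------------------------------------------------------------------------
# Reverse lookup
# ---------------------------------------------------------------------------

def estimate_pressures(
    fit: GaussianEnvelopeFit,
    coeffs: AmplitudeCoefficients = DEFAULT_COEFFICIENTS,
) -> tuple[float, float]:
    """Systolic/diastolic pressures from the fitted envelope.

    SP is where the envelope falls to Ks*y_max above the peak, DP where it
    falls to Kd*y_max below it (closed-form inversion of the Gaussian).
    """
    sp = fit.x_max + math.sqrt(fit.s * math.log(1.0 / coeffs.ks))
    dp = fit.x_max - math.sqrt(fit.s * math.log(1.0 / coeffs.kd))
    return sp, dp


def estimate_blood_pressure(
    recording: CuffDeflationRecording,
    coeffs: AmplitudeCoefficients = DEFAULT_COEFFICIENTS,
) -> tuple[BloodPressureEstimate, GaussianEnvelopeFit, PulseEnvelope]:
    """Full pipeline: separate, extract, fit, reverse-lookup, heart rate."""
    static, dynamic = separate_components(recording)
    envelope = extract_envelope(static, dynamic, recording.sample_rate)
    fit = fit_envelope(envelope)
    sp, dp = estimate_pressures(fit, coeffs)
    hr = estimate_heart_rate(dynamic, recording.sample_rate)
    estimate = BloodPressureEstimate(sp=sp, dp=dp, peak_pressure=fit.x_max, hr=hr)
    return estimate, fit, envelope


# ---------------------------------------------------------------------------
# Cuff simulation
# ---------------------------------------------------------------------------

def solve_envelope_geometry(
    sp: float,
    dp: float,
    coeffs: AmplitudeCoefficients = DEFAULT_COEFFICIENTS,
) -> tuple[float, float]:
    """Envelope (x_max, s) whose reverse lookup yields exactly (sp, dp).

    Inverts the two threshold equations: with a = ln(1/Ks), d = ln(1/Kd),
    SP - x_max = sqrt(s*a) and x_max - DP = sqrt(s*d), so the peak divides
    [DP, SP] in the ratio sqrt(a):sqrt(d).
    """
    a = math.log(1.0 / coeffs.ks)
    d = math.log(1.0 / coeffs.kd)
    r = math.sqrt(a / d)
    x_max = (sp + r * dp) / (1.0 + r)
    s = (sp - x_max) ** 2 / a
    return x_max, s


def simulate_recording(
    true_sp: float,
    true_dp: float,
    hr: float,
    envelope_s: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    coeffs: AmplitudeCoefficients = DEFAULT_COEFFICIENTS,
    sample_rate: float = 100.0,
    deflation_rate: float = 3.0,
    peak_amplitude: float = 3.0,
) -> CuffDeflationRecording:
    """Simulate a cuff-deflation recording with a Gaussian pulse envelope.

    The cuff deflates linearly from true_SP + 50 mmHg down to true_DP - 55
    mmHg (clamped positive) at ``deflation_rate`` mmHg/s; a pulse train at the given heart rate
    rides on the ramp with amplitude following a Gaussian envelope in cuff
    pressure. By default the envelope peak position and width are solved so
    that the default-coefficient reverse lookup recovers (true_SP, true_DP)
    exactly in the noiseless case. An explicit ``envelope_s`` overrides the
    width; the peak is then placed from the systolic equation alone, so only
    SP round-trips exactly.

    White Gaussian sensor noise of sd ``noise_sd`` mmHg is added to the
    composite signal. Deterministic for a fixed seed.
    """
    if not true_dp < true_sp:
        raise ValueError(f"need DP < SP, got SP={true_sp}, DP={true_dp}")
    if not HR_MIN_BPM <= hr <= HR_MAX_BPM:
        raise ValueError(f"heart rate {hr} bpm outside [{HR_MIN_BPM}, {HR_MAX_BPM}]")

    a = math.log(1.0 / coeffs.ks)
    if envelope_s is None:
        x_max, s = solve_envelope_geometry(true_sp, true_dp, coeffs)
    else:
        if envelope_s <= 0:
            raise ValueError("envelope_s must be positive")
        s = float(envelope_s)
        x_max = true_sp - math.sqrt(s * a)

    # Overshoot on both sides keeps every detectable pulse clear of the
    # envelope extractor's edge margins.
    start = true_sp + 50.0
    end = max(true_dp - 55.0, 5.0)
    duration = (start - end) / deflation_rate
    n = int(round(duration * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    ramp = start - deflation_rate * t

    # Zero-mean oscillation carrier at the pulse rate; peak-to-trough
    # amplitude at cuff pressure p is the Gaussian envelope value.
    amplitude = peak_amplitude * np.exp(-((ramp - x_max) ** 2) / s)
    carrier = np.cos(2.0 * np.pi * (hr / 60.0) * t)
    dynamic = 0.5 * amplitude * carrier

    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0
    pressure = ramp + dynamic + noise

    pulse_times = np.arange(0.0, duration + 1e-9, 60.0 / hr)
    pulse_pressures = start - deflation_rate * pulse_times
    truth = SimulationTruth(
        sp=true_sp, dp=true_dp, hr=hr, x_max=x_max, s=s,
        y_max=peak_amplitude, pulse_pressures=pulse_pressures,
    )
    return CuffDeflationRecording(
        time=t, pressure=pressure, sample_rate=sample_rate, truth=truth
    )


# ---------------------------------------------------------------------------
# Recording I/O
# ---------------------------------------------------------------------------

def write_recording_csv(recording: CuffDeflationRecording, path) -> None:
    """Two-column CSV (time_s, pressure_mmHg) with header."""
    pd.DataFrame(
        {"time_s": recording.time, "pressure_mmHg": recording.pressure}
    ).to_csv(path, index=False)


def read_recording_csv(path) -> CuffDeflationRecording:
    """Read a two-column recording CSV; sample rate inferred from the time axis."""
    df = pd.read_csv(path)
    for col in ("time_s", "pressure_mmHg"):
        if col not in df.columns:
            raise ValueError(f"recording CSV missing column {col!r}")
    time = df["time_s"].to_numpy(dtype=float)
    if time.size < 2:
        raise ValueError("recording CSV needs at least 2 samples")
    sample_rate = 1.0 / float(np.median(np.diff(time)))
    return CuffDeflationRecording(
        time=time,
        pressure=df["pressure_mmHg"].to_numpy(dtype=float),
        sample_rate=sample_rate,
    )
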