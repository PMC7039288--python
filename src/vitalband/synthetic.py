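"""Ground-truth-known synthetic sensor streams.

Every downstream stage (PPG heart rate / SpO2, activity classification,
temperature bias correction, GSR trending) is validated against signals
built here, where the truth — pulse frequency, modulation ratio, per-axis
acceleration extremes, core-temperature offset, conductance rise — is a
construction parameter rather than an unknown.

Signal models
-------------
* PPG: per beat, a primary systolic Gaussian bump plus a smaller, wider
  secondary diastolic bump, repeated periodically at the pulse frequency and
  superposed on a steady DC level; optional additive white Gaussian noise,
  independent per wavelength.  The pulse train is normalized so that the
  mean detected-peak height above the signal mean equals one, which makes
  ``perfusion x DC`` exactly the AC amplitude the downstream peak-averaging
  extractor measures, and the ground-truth modulation ratio exactly
  ``perfusion_red / perfusion_ir``.
* Accelerometry: per axis, samples uniform within the reference range for
  the requested intensity level, with the two range endpoints explicitly
  planted so min/max features are exact; a jitter fraction widens or
  shrinks each endpoint by up to that fraction of the axis range.
* Skin temperature: baseline plus a Gaussian random-walk drift; the latent
  core truth is skin + a fixed offset.
* GSR: baseline conductance with a trapezoidal rise of a given height
  inside an exercise interval (linear on/off ramps), quantized to the
  10-bit ADC code space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activity import TABLE1_RANGES_MG
from .gsr import conductance_to_adc
from .ppg import PEAK_MIN_PROMINENCE_FRAC, PEAK_MIN_SPACING_S
from .types import AccelWindow, DualPPG, GSRSeries, TempSeries

__all__ = [
    "PPGSpec",
    "AccelSpec",
    "TempGSRSpec",
    "generate_ppg",
    "generate_accel",
    "generate_temp_gsr",
]

# Pulse morphology (fractions of one beat period).  The systolic bump is
# narrow and tall; the diastolic bump arrives just before mid-diastole and
# is wider and smaller, giving the classic two-peak reflectance waveform
# while keeping the spectral fundamental dominant over its harmonics.
_SYSTOLIC_WIDTH_FRAC = 0.15
_DIASTOLIC_WIDTH_FRAC = 0.20
_DIASTOLIC_DELAY_FRAC = 0.45


@dataclass(frozen=True)
class PPGSpec:
    """Construction parameters for a dual-wavelength photoplethysmogram.

    ``perfusion_red`` / ``perfusion_ir`` are the pulsatile amplitudes as
    fractions of the corresponding DC level; their quotient is the
    ground-truth modulation ratio.
    """

    heart_rate_bpm: float = 80.52
    duration_s: float = 40.0
    fs_hz: float = 50.0
    dc_red: float = 1000.0
    dc_ir: float = 1000.0
    perfusion_red: float = 0.01
    perfusion_ir: float = 0.02
    diastolic_fraction: float = 0.3
    noise_sd: float = 0.0
    seed: int | None = None

    def validate(self) -> None:
        if self.heart_rate_bpm <= 0:
            raise ValueError("heart_rate_bpm must be positive")
        if self.fs_hz <= 2.0 * self.heart_rate_bpm / 60.0:
            raise ValueError(
                "Nyquist violation: fs_hz must exceed twice the pulse frequency"
            )
        if self.dc_red <= 0 or self.dc_ir <= 0:
            raise ValueError("DC levels must be positive")
        for name in ("perfusion_red", "perfusion_ir"):
            f = getattr(self, name)
            if not 0.0 < f < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not 0.0 <= self.diastolic_fraction < 1.0:
            raise ValueError("diastolic_fraction must lie in [0, 1)")
        if self.duration_s <= 0 or self.noise_sd < 0:
            raise ValueError("duration_s must be positive, noise_sd non-negative")


@dataclass(frozen=True)
class AccelSpec:
    """Construction parameters for one labeled accelerometry window."""

    level: int
    duration_s: float = 30.0
    fs_hz: float = 10.0
    jitter_frac: float = 0.0
    seed: int | None = None

    def validate(self) -> None:
        if self.level not in TABLE1_RANGES_MG:
            raise ValueError(f"unknown intensity level {self.level!r}")
        if self.jitter_frac < 0:
            raise ValueError("jitter_frac must be non-negative")
        if self.duration_s <= 0 or self.fs_hz <= 0:
            raise ValueError("duration_s and fs_hz must be positive")


@dataclass(frozen=True)
class TempGSRSpec:
    """Construction parameters for skin-temperature and GSR traces."""

    duration_s: float = 300.0
    fs_hz: float = 1.0
    skin_baseline_c: float = 32.48
    core_offset_c: float = 4.14
    drift_sd: float = 0.0
    gsr_baseline_us: float = 2.0
    gsr_rise_us: float = 3.0
    exercise_interval: tuple[float, float] = (120.0, 240.0)
    ramp_s: float = 5.0
    seed: int | None = None

    def validate(self) -> None:
        if not 22.0 <= self.skin_baseline_c <= 40.0:
            raise ValueError(
                "skin_baseline_c outside the thermopile's 22-40 degC range"
            )
        lo, hi = self.exercise_interval
        if not 0.0 <= lo < hi <= self.duration_s:
            raise ValueError("exercise_interval must lie within the duration")
        if not (
            1.0 <= self.gsr_baseline_us
            and self.gsr_baseline_us + self.gsr_rise_us <= 16.0
        ):
            raise ValueError("GSR conductance must stay within 1-16 uS")
        if self.drift_sd < 0 or self.ramp_s < 0:
            raise ValueError("drift_sd and ramp_s must be non-negative")


def _pulse_train(n: int, fs_hz: float, heart_rate_bpm: float,
                 diastolic_fraction: float) -> np.ndarray:
    """Zero-mean periodic two-bump pulse train normalized so the mean
    detected-peak height above the mean is exactly one."""
    from scipy.signal import find_peaks

    period_s = 60.0 / heart_rate_bpm
    phase = (np.arange(n) / fs_hz / period_s) % 1.0

    def bump(center: float, width: float) -> np.ndarray:
        d = np.abs(phase - center)
        d = np.minimum(d, 1.0 - d)  # wrapped phase distance
        return np.exp(-0.5 * (d / width) ** 2)

    p = bump(0.5, _SYSTOLIC_WIDTH_FRAC)
    if diastolic_fraction > 0:
        p = p + diastolic_fraction * bump(
            (0.5 + _DIASTOLIC_DELAY_FRAC) % 1.0, _DIASTOLIC_WIDTH_FRAC
        )
    p = p - p.mean()
    max_dev = np.abs(p).max()
    peaks, _ = find_peaks(
        p,
        distance=max(1, int(round(PEAK_MIN_SPACING_S * fs_hz))),
        prominence=PEAK_MIN_PROMINENCE_FRAC * max_dev,
    )
    if peaks.size == 0:  # degenerate (very short series); fall back to max
        scale = max_dev
    else:
        scale = float(np.mean(p[peaks]))
    return p / scale


def generate_ppg(spec: PPGSpec) -> DualPPG:
    """Synthesize a dual-wavelength PPG with known pulse frequency and
    modulation ratio.

    Each wavelength is ``DC x (1 + perfusion x pulse_train) + noise`` with
    the same normalized pulse train, so the ground-truth modulation ratio is
    ``perfusion_red / perfusion_ir`` independent of morphology.
    """
    spec.validate()
    n = int(round(spec.duration_s * spec.fs_hz))
    t = np.arange(n) / spec.fs_hz
    pulse = _pulse_train(n, spec.fs_hz, spec.heart_rate_bpm, spec.diastolic_fraction)
    rng = np.random.default_rng(spec.seed)
    red = spec.dc_red * (1.0 + spec.perfusion_red * pulse)
    ir = spec.dc_ir * (1.0 + spec.perfusion_ir * pulse)
    if spec.noise_sd > 0:
        red = red + rng.normal(0.0, spec.noise_sd, n)
        ir = ir + rng.normal(0.0, spec.noise_sd, n)
    return DualPPG(
        t=t,
        red=red,
        ir=ir,
        fs_hz=spec.fs_hz,
        true_heart_rate_bpm=spec.heart_rate_bpm,
        true_modulation_ratio=spec.perfusion_red / spec.perfusion_ir,
    )


def generate_accel(spec: AccelSpec) -> AccelWindow:
    """Synthesize one labeled tri-axial window for an intensity level.

    With ``jitter_frac = 0`` the per-axis extremes equal the reference
    range endpoints exactly (they are planted, not sampled); with jitter,
    each endpoint moves uniformly by up to ``jitter_frac`` of the axis
    range before planting and filling.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs_hz))
    if n < 2:
        raise ValueError("window must contain at least two samples")
    t = np.arange(n) / spec.fs_hz
    axes = {}
    ranges = TABLE1_RANGES_MG[spec.level]
    for axis in ("x", "y", "z"):
        lo, hi = ranges[axis]
        width = hi - lo
        jitter = spec.jitter_frac * width
        lo_eff = lo + rng.uniform(-jitter, jitter) if jitter > 0 else lo
        hi_eff = hi + rng.uniform(-jitter, jitter) if jitter > 0 else hi
        samples = rng.uniform(lo_eff, hi_eff, n)
        i_lo, i_hi = rng.choice(n, size=2, replace=False)
        samples[i_lo] = lo_eff  # plant exact extremes
        samples[i_hi] = hi_eff
        axes[axis] = samples
    return AccelWindow(
        t=t, x=axes["x"], y=axes["y"], z=axes["z"], fs_hz=spec.fs_hz,
        label=spec.level,
    )


def generate_temp_gsr(spec: TempGSRSpec) -> tuple[TempSeries, GSRSeries]:
    """Synthesize skin-temperature and GSR traces with known truths.

    Skin temperature is baseline plus a random-walk drift (step SD
    ``drift_sd / sqrt(fs_hz)`` degC, so the drift scale is per square-root
    second); the latent core truth is skin + ``core_offset_c``.  GSR is
    baseline conductance with a trapezoidal rise of ``gsr_rise_us`` inside
    the exercise interval, linear ramps of ``ramp_s`` on either edge,
    quantized to ADC codes.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs_hz))
    t = np.arange(n) / spec.fs_hz

    if spec.drift_sd > 0:
        drift = np.cumsum(rng.normal(0.0, spec.drift_sd / np.sqrt(spec.fs_hz), n))
    else:
        drift = np.zeros(n)
    skin = spec.skin_baseline_c + drift
    temp = TempSeries(
        t=t, skin_c=skin, fs_hz=spec.fs_hz, core_truth_c=skin + spec.core_offset_c
    )

    start, end = spec.exercise_interval
    ramp = max(spec.ramp_s, 1.0 / spec.fs_hz)
    up = np.clip((t - start) / ramp, 0.0, 1.0)
    down = np.clip((end + ramp - t) / ramp, 0.0, 1.0)
    conductance = spec.gsr_baseline_us + spec.gsr_rise_us * np.minimum(up, down)
    codes = conductance_to_adc(conductance)
    gsr = GSRSeries(
        t=t,
        fs_hz=spec.fs_hz,
        code=codes,
        true_conductance_us=conductance,
    )
    return temp, gsr
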