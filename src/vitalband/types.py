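"""Core in-memory containers for device signals and derived quantities.

All containers are plain dataclasses over numpy arrays.  Time is seconds from
session start; acceleration is milli-g; temperature is degrees Celsius; skin
conductance is microsiemens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DualPPG",
    "Spectrum",
    "ACDCComponents",
    "HeartRateEstimate",
    "WindowedHeartRate",
    "SpO2Estimate",
    "AccelWindow",
    "FeatureVector",
    "ClassifierReport",
    "TempSeries",
    "GSRSeries",
]


@dataclass
class DualPPG:
    """Paired red / infrared photoplethysmogram sampled at a fixed rate.

    The pulsatile (AC) component of each waveform tracks arterial blood
    volume; the steady (DC) component tracks baseline tissue reflectance.
    Synthetic instances carry the construction ground truth so downstream
    estimators can be validated end to end.
    """

    t: np.ndarray
    red: np.ndarray
    ir: np.ndarray
    fs_hz: float = 50.0
    true_heart_rate_bpm: float | None = None
    true_modulation_ratio: float | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.red = np.asarray(self.red, dtype=float)
        self.ir = np.asarray(self.ir, dtype=float)
        if self.red.shape != self.ir.shape:
            raise ValueError("red and ir series must have equal length")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")

    @property
    def duration_s(self) -> float:
        return self.red.size / self.fs_hz

    def channel(self, wavelength: str) -> np.ndarray:
        if wavelength not in ("red", "ir"):
            raise ValueError(f"unknown wavelength {wavelength!r}")
        return self.red if wavelength == "red" else self.ir


@dataclass
class Spectrum:
    """Single-sided amplitude spectrum on a uniform frequency grid."""

    freq_hz: np.ndarray
    amplitude: np.ndarray
    resolution_hz: float

    def __post_init__(self):
        self.freq_hz = np.asarray(self.freq_hz, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.freq_hz.size and self.freq_hz[0] < 0:
            raise ValueError("frequency grid must be non-negative")


@dataclass
class ACDCComponents:
    """Per-wavelength pulsatile (AC) and steady (DC) amplitudes over one
    averaging interval.  An undetectable AC component (no pulse peaks found)
    is stored as NaN and the interval is flagged invalid for that wavelength.
    """

    ac_red: float
    dc_red: float
    ac_ir: float
    dc_ir: float
    interval_s: float = 10.0
    start_s: float = 0.0

    @property
    def red_valid(self) -> bool:
        return math.isfinite(self.ac_red)

    @property
    def ir_valid(self) -> bool:
        return math.isfinite(self.ac_ir)

    @property
    def valid(self) -> bool:
        return self.red_valid and self.ir_valid


@dataclass
class HeartRateEstimate:
    """Heart rate from the spectral peak: bpm = 60 x peak frequency."""

    bpm: float
    peak_freq_hz: float
    window_start_s: float = 0.0
    window_end_s: float = 0.0


@dataclass
class WindowedHeartRate:
    """Heart-rate estimates over consecutive fixed-length windows, with
    means over longer averaging spans."""

    estimates: list[HeartRateEstimate]
    span_means: list[tuple[float, float, float]]  # (start_s, end_s, mean bpm)

    @property
    def mean_bpm(self) -> float:
        return float(np.mean([e.bpm for e in self.estimates]))


@dataclass
class SpO2Estimate:
    """Blood-oxygen saturation estimate in percent.

    ``spo2`` is clamped to [0, 100] for reporting; ``spo2_unclamped`` keeps
    the raw value of the linear ratio-of-ratios formula, which exceeds 100
    for modulation ratios below 0.4.
    """

    spo2: float
    spo2_unclamped: float
    ratio: float

    def __float__(self) -> float:
        return self.spo2


@dataclass
class AccelWindow:
    """A fixed-duration tri-axial acceleration segment in milli-g.

    Axis semantics follow the armband mounting: x is medial/lateral,
    y anterior/posterior, z superior/inferior.  ``label`` is the optional
    activity-intensity level (1-5).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    fs_hz: float = 10.0
    label: int | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (self.x.shape == self.y.shape == self.z.shape):
            raise ValueError("x, y, z axes must have equal length")


@dataclass(frozen=True)
class FeatureVector:
    """Six min/max accelerometry features (mg) used by the intensity SVM."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    z_min: float
    z_max: float

    def __post_init__(self):
        for axis in "xyz":
            if getattr(self, f"{axis}_min") > getattr(self, f"{axis}_max"):
                raise ValueError(f"{axis}_min exceeds {axis}_max")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.x_min, self.x_max, self.y_min, self.y_max, self.z_min, self.z_max],
            dtype=float,
        )


@dataclass
class ClassifierReport:
    """Held-out evaluation of the activity-intensity classifier.

    ``confusion`` is a 5x5 count matrix with true class on rows and
    predicted class on columns, levels 1..5 in order.
    """

    accuracy: float
    confusion: np.ndarray
    split_seed: int | None
    n_train: int
    n_test: int

    def __post_init__(self):
        self.confusion = np.asarray(self.confusion, dtype=int)
        if self.confusion.sum() != self.n_test:
            raise ValueError("confusion entries must sum to n_test")


@dataclass
class TempSeries:
    """Skin-temperature series (deg C); synthetic instances also carry the
    latent core-temperature truth used to validate bias correction."""

    t: np.ndarray
    skin_c: np.ndarray
    fs_hz: float = 1.0
    core_truth_c: np.ndarray | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.skin_c = np.asarray(self.skin_c, dtype=float)
        if self.core_truth_c is not None:
            self.core_truth_c = np.asarray(self.core_truth_c, dtype=float)


@dataclass
class GSRSeries:
    """Galvanic-skin-response series: raw 10-bit ADC codes and/or skin
    conductance in microsiemens."""

    t: np.ndarray
    fs_hz: float = 1.0
    code: np.ndarray | None = None
    conductance_us: np.ndarray | None = None
    true_conductance_us: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        if self.code is None and self.conductance_us is None:
            raise ValueError("GSRSeries needs codes or conductance values")
        if self.code is not None:
            self.code = np.asarray(self.code)
        if self.conductance_us is not None:
            self.conductance_us = np.asarray(self.conductance_us, dtype=float)
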