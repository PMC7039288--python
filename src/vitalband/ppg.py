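"""Heart rate and blood-oxygen saturation from dual-wavelength PPG.

The processing chain mirrors reflectance pulse oximetry practice:

* heart rate — the photoplethysmogram is mean-subtracted, zero-padded and
  transformed with an FFT; the peak of the single-sided amplitude spectrum
  inside a physiological band (default 0.5-3.5 Hz, i.e. 30-210 bpm) gives
  the pulse frequency, and heart rate = 60 x frequency.
* SpO2 — each waveform is split into a steady (DC) level, the mean over a
  10-s interval, and a pulsatile (AC) amplitude, the mean height of detected
  pulse peaks above that level.  The modulation ratio
  R = (AC_red/DC_red) / (AC_ir/DC_ir) is a proxy for the deoxy/oxy
  hemoglobin absorbance ratio, and saturation follows the linear empirical
  map SpO2 = 110 - 25 R.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .exceptions import UndefinedRatioError
from .types import (
    ACDCComponents,
    DualPPG,
    HeartRateEstimate,
    SpO2Estimate,
    Spectrum,
    WindowedHeartRate,
)

__all__ = [
    "single_sided_spectrum",
    "estimate_heart_rate",
    "windowed_heart_rate",
    "extract_ac_dc",
    "modulation_ratio",
    "spo2_from_ratio",
    "DEFAULT_HR_BAND_HZ",
    "PEAK_MIN_SPACING_S",
    "PEAK_MIN_PROMINENCE_FRAC",
]

#: Physiological heart-rate search band: 0.5-3.5 Hz <-> 30-210 bpm.
DEFAULT_HR_BAND_HZ = (0.5, 3.5)

#: Pulse-peak detector: minimum inter-peak spacing (caps rate at 240 bpm)
#: and minimum prominence as a fraction of the interval's max deviation.
PEAK_MIN_SPACING_S = 0.25
PEAK_MIN_PROMINENCE_FRAC = 0.10


def single_sided_spectrum(
    signal: Sequence[float],
    fs_hz: float,
    target_resolution_hz: float = 0.002,
) -> Spectrum:
    """Single-sided amplitude spectrum of a mean-subtracted signal.

    The signal is zero-padded so the frequency-grid spacing is at most
    ``target_resolution_hz`` (the 0.025 Hz native resolution of a 40-s
    window is too coarse for sub-bpm heart-rate readout).  Amplitudes are
    scaled by the *original* length, so a pure sinusoid of amplitude ``a``
    shows a peak of approximately ``a``.  No taper is applied.

    Parameters
    ----------
    signal : array-like
        At least two samples, uniformly sampled at ``fs_hz``.
    fs_hz : float
        Sampling rate in Hz.
    target_resolution_hz : float
        Maximum spacing of the output frequency grid.

    Returns
    -------
    Spectrum
        Non-negative frequency grid and one-sided amplitudes.  A constant
        signal yields an all-zero spectrum (not an error).
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("signal must be one-dimensional with >= 2 samples")
    if fs_hz <= 0 or target_resolution_hz <= 0:
        raise ValueError("fs_hz and target_resolution_hz must be positive")
    n = x.size
    x = x - x.mean()
    n_fft = max(n, int(np.ceil(fs_hz / target_resolution_hz)))
    amp = np.abs(np.fft.rfft(x, n_fft)) / n
    # one-sided: double every bin except DC (and Nyquist for even n_fft)
    amp[1:] *= 2.0
    if n_fft % 2 == 0:
        amp[-1] /= 2.0
    freq = np.fft.rfftfreq(n_fft, d=1.0 / fs_hz)
    return Spectrum(freq_hz=freq, amplitude=amp, resolution_hz=fs_hz / n_fft)


def estimate_heart_rate(
    spectrum: Spectrum,
    band_hz: tuple[float, float] = DEFAULT_HR_BAND_HZ,
) -> HeartRateEstimate:
    """Heart rate from the spectral peak inside a closed frequency band.

    bpm = 60 x argmax frequency; both band edges are inclusive and amplitude
    ties resolve toward the lower frequency, so repeated calls are
    deterministic.
    """
    lo, hi = band_hz
    if lo > hi:
        raise ValueError("band lower edge exceeds upper edge")
    if lo < spectrum.freq_hz[0] or hi > spectrum.freq_hz[-1]:
        raise ValueError("band lies outside the spectrum's frequency grid")
    mask = (spectrum.freq_hz >= lo) & (spectrum.freq_hz <= hi)
    freqs = spectrum.freq_hz[mask]
    amps = spectrum.amplitude[mask]
    peak = freqs[int(np.argmax(amps))]  # argmax returns first max: lowest f
    return HeartRateEstimate(bpm=60.0 * peak, peak_freq_hz=float(peak))


def windowed_heart_rate(
    ppg: DualPPG,
    wavelength: str = "ir",
    window_s: float = 40.0,
    average_over_s: float = 300.0,
    band_hz: tuple[float, float] = DEFAULT_HR_BAND_HZ,
    target_resolution_hz: float = 0.002,
) -> WindowedHeartRate:
    """Per-window heart-rate estimates with means over longer spans.

    The series is cut into consecutive non-overlapping windows of
    ``window_s`` seconds (half-open in time, trailing partial window
    dropped); each window yields one spectral-peak estimate.  Estimates are
    then averaged over consecutive ``average_over_s`` spans — the scheme
    used to compare 40-s device estimates to 5-min-averaged reference pulse
    rates.
    """
    x = ppg.channel(wavelength)
    step = int(round(window_s * ppg.fs_hz))
    if step < 2 or x.size < step:
        raise ValueError("signal shorter than one analysis window")
    estimates = []
    for k in range(x.size // step):
        seg = x[k * step : (k + 1) * step]
        est = estimate_heart_rate(
            single_sided_spectrum(seg, ppg.fs_hz, target_resolution_hz), band_hz
        )
        est.window_start_s = k * window_s
        est.window_end_s = (k + 1) * window_s
        estimates.append(est)

    span_means = []
    per_span = max(1, int(round(average_over_s / window_s)))
    for k in range(0, len(estimates), per_span):
        chunk = estimates[k : k + per_span]
        span_means.append(
            (
                chunk[0].window_start_s,
                chunk[-1].window_end_s,
                float(np.mean([e.bpm for e in chunk])),
            )
        )
    return WindowedHeartRate(estimates=estimates, span_means=span_means)


def _interval_ac_dc(seg: np.ndarray, fs_hz: float) -> tuple[float, float]:
    """DC (interval mean) and AC (mean detected-peak height above DC) for a
    single wavelength over one interval.  AC is NaN when no peak passes the
    spacing/prominence gates (flat or pulseless segment)."""
    dc = float(seg.mean())
    deviation = np.abs(seg - dc)
    max_dev = float(deviation.max())
    if max_dev == 0.0:
        return np.nan, dc
    peaks, _ = find_peaks(
        seg,
        distance=max(1, int(round(PEAK_MIN_SPACING_S * fs_hz))),
        prominence=PEAK_MIN_PROMINENCE_FRAC * max_dev,
    )
    if peaks.size == 0:
        return np.nan, dc
    return float(np.mean(seg[peaks] - dc)), dc


def extract_ac_dc(ppg: DualPPG, interval_s: float = 10.0) -> list[ACDCComponents]:
    """Split both wavelengths into consecutive intervals and measure the
    steady and pulsatile components of each.

    Per interval and wavelength: DC is the interval mean; AC is the mean
    height of detected pulse peaks above DC.  Intervals where a wavelength
    has no detectable peaks carry ``ac = NaN`` and are flagged invalid so
    downstream saturation averaging can skip them.
    """
    step = int(round(interval_s * ppg.fs_hz))
    if step < 2 or ppg.red.size < step:
        raise ValueError("signal shorter than one averaging interval")
    out = []
    for k in range(ppg.red.size // step):
        sl = slice(k * step, (k + 1) * step)
        ac_r, dc_r = _interval_ac_dc(ppg.red[sl], ppg.fs_hz)
        ac_i, dc_i = _interval_ac_dc(ppg.ir[sl], ppg.fs_hz)
        out.append(
            ACDCComponents(
                ac_red=ac_r,
                dc_red=dc_r,
                ac_ir=ac_i,
                dc_ir=dc_i,
                interval_s=interval_s,
                start_s=k * interval_s,
            )
        )
    return out


def modulation_ratio(c: ACDCComponents) -> float:
    """Ratio of ratios R = (AC_red/DC_red) / (AC_ir/DC_ir).

    Raises
    ------
    UndefinedRatioError
        If either AC is undefined (flagged interval) or AC_ir is zero.
    """
    if not c.valid:
        raise UndefinedRatioError("AC undefined for at least one wavelength")
    if c.dc_red <= 0 or c.dc_ir <= 0:
        raise ValueError("DC levels must be positive")
    if c.ac_ir == 0:
        raise UndefinedRatioError("infrared AC amplitude is zero")
    return (c.ac_red / c.dc_red) / (c.ac_ir / c.dc_ir)


def spo2_from_ratio(ratio: float) -> SpO2Estimate:
    """Blood-oxygen saturation from the modulation ratio: SpO2 = 110 - 25 R.

    The reported value is clamped to [0, 100] percent (the linear map
    exceeds 100 for R < 0.4); the unclamped value is retained alongside.
    """
    if ratio < 0:
        raise ValueError("modulation ratio must be non-negative")
    raw = 110.0 - 25.0 * ratio
    return SpO2Estimate(
        spo2=float(np.clip(raw, 0.0, 100.0)), spo2_unclamped=raw, ratio=ratio
    )
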