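"""Galvanic skin response: ADC codes to conductance, baseline deviation.

The GSR front end digitizes skin conductance to 10-bit codes spanning
1-16 microsiemens.  The code-to-conductance map is declared linear here
(the analog transfer of the op-amp/potentiometer front end is a device
detail); what the analysis consumes is the *deviation* from an individual
baseline, a relative-hydration trend that rises with perspiration.
"""

from __future__ import annotations

import numpy as np

from .types import GSRSeries

__all__ = [
    "GSR_RANGE_US",
    "ADC_MAX_CODE",
    "adc_to_conductance",
    "conductance_to_adc",
    "baseline_deviation",
]

GSR_RANGE_US = (1.0, 16.0)
ADC_MAX_CODE = 1023


def adc_to_conductance(code):
    """Map 10-bit ADC codes onto skin conductance in microsiemens.

    Linear with exact endpoints: code 0 -> 1 uS, code 1023 -> 16 uS.
    Accepts scalars or arrays; codes outside [0, 1023] are rejected.
    """
    c = np.asarray(code, dtype=float)
    if np.any(c < 0) or np.any(c > ADC_MAX_CODE):
        raise ValueError(f"ADC codes must lie in [0, {ADC_MAX_CODE}]")
    lo, hi = GSR_RANGE_US
    out = lo + (hi - lo) * c / ADC_MAX_CODE
    return float(out) if np.isscalar(code) else out


def conductance_to_adc(conductance_us):
    """Inverse of :func:`adc_to_conductance`, rounded to integer codes."""
    g = np.asarray(conductance_us, dtype=float)
    lo, hi = GSR_RANGE_US
    if np.any(g < lo) or np.any(g > hi):
        raise ValueError(f"conductance must lie in [{lo}, {hi}] uS")
    codes = np.rint((g - lo) / (hi - lo) * ADC_MAX_CODE).astype(int)
    return int(codes) if np.isscalar(conductance_us) else codes


def _conductance(series: GSRSeries) -> np.ndarray:
    if series.conductance_us is not None:
        return np.asarray(series.conductance_us, dtype=float)
    return adc_to_conductance(series.code)


def baseline_deviation(
    series: GSRSeries,
    baseline_window_s: tuple[float, float] = (0.0, 60.0),
    smooth_s: float | None = None,
) -> np.ndarray:
    """Conductance deviation from an individual's baseline, in uS.

    Delta(t) = conductance(t) - mean conductance over the (half-open)
    baseline window.  ``smooth_s``, if given, applies a centered moving
    average of that width to the deviation series; a width of one sample or
    less leaves the series unchanged.
    """
    g = _conductance(series)
    lo, hi = baseline_window_s
    mask = (series.t >= lo) & (series.t < hi)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    delta = g - g[mask].mean()
    if smooth_s is not None:
        width = int(round(smooth_s * series.fs_hz))
        if width > 1:
            kernel = np.ones(width) / width
            # edge-padded so the smoothed series keeps its length and scale
            padded = np.pad(delta, (width // 2, width - 1 - width // 2), mode="edge")
            delta = np.convolve(padded, kernel, mode="valid")
    return delta
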