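"""End-to-end session analysis: one device log in, one report out.

:func:`analyze_session` runs the four analysis stages — PPG heart rate and
SpO2, temperature bias correction, activity classification, GSR baseline
deviation — over a :class:`~vitalband.io.DeviceLog`.  Stages are
independent: a failing or unavailable stage is recorded in the report's
``errors`` and the rest still run.  Reports are pure functions of
(log, config, models); identical inputs give byte-identical JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import __version__
from .activity import IntensityClassifier, classify, extract_features
from .calibration import BiasCorrector
from .gsr import baseline_deviation
from .io import DeviceLog
from .ppg import extract_ac_dc, modulation_ratio, spo2_from_ratio, windowed_heart_rate
from .types import AccelWindow

__all__ = ["SessionConfig", "SessionReport", "analyze_session"]


@dataclass(frozen=True)
class SessionConfig:
    """Analysis parameters and optional correction models for one session.

    Windows are half-open ``[start, end)`` seconds.  Bias terms are in the
    target's units (percent SpO2, deg C); ``hr_calibration`` is a
    ``{"slope": ..., "intercept": ...}`` mapping device bpm to reference
    bpm.  Calibrated/corrected series appear in the report only when the
    corresponding model is supplied.
    """

    hr_wavelength: str = "ir"
    hr_band_hz: tuple[float, float] = (0.5, 3.5)
    hr_window_s: float = 40.0
    hr_average_s: float = 300.0
    spectrum_resolution_hz: float = 0.002
    spo2_interval_s: float = 10.0
    activity_window_s: float = 30.0
    gsr_baseline_window_s: tuple[float, float] = (0.0, 60.0)
    gsr_smooth_s: float | None = None
    spo2_bias: float | None = None
    temp_bias_c: float | None = None
    hr_calibration: dict[str, float] | None = None

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SessionReport:
    """Per-session derived metrics, each row tagged with its window."""

    hr: dict[str, Any] | None = None
    spo2: dict[str, Any] | None = None
    core_temp: dict[str, Any] | None = None
    activity: dict[str, Any] | None = None
    gsr: dict[str, Any] | None = None
    errors: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _hr_stage(log: DeviceLog, config: SessionConfig) -> dict | None:
    ppg = log.ppg()
    if ppg is None:
        return None
    result = windowed_heart_rate(
        ppg,
        wavelength=config.hr_wavelength,
        window_s=config.hr_window_s,
        average_over_s=config.hr_average_s,
        band_hz=config.hr_band_hz,
        target_resolution_hz=config.spectrum_resolution_hz,
    )
    cal = config.hr_calibration
    windows = []
    for est in result.estimates:
        row = {
            "window_start_s": est.window_start_s,
            "window_end_s": est.window_end_s,
            "bpm_raw": est.bpm,
            "peak_freq_hz": est.peak_freq_hz,
        }
        if cal is not None:
            row["bpm_calibrated"] = cal["slope"] * est.bpm + cal["intercept"]
        windows.append(row)
    return {
        "wavelength": config.hr_wavelength,
        "windows": windows,
        "span_means_bpm": [
            {"start_s": s, "end_s": e, "mean_bpm": m} for s, e, m in result.span_means
        ],
        "mean_bpm": result.mean_bpm,
    }


def _spo2_stage(log: DeviceLog, config: SessionConfig) -> dict | None:
    ppg = log.ppg()
    if ppg is None:
        return None
    intervals = []
    raws = []
    for c in extract_ac_dc(ppg, interval_s=config.spo2_interval_s):
        row: dict[str, Any] = {
            "start_s": c.start_s,
            "end_s": c.start_s + c.interval_s,
            "valid": c.valid,
        }
        if c.valid:
            ratio = modulation_ratio(c)
            est = spo2_from_ratio(ratio)
            row.update(ratio=ratio, spo2_raw=est.spo2,
                       spo2_unclamped=est.spo2_unclamped)
            if config.spo2_bias is not None:
                row["spo2_corrected"] = float(
                    np.clip(est.spo2_unclamped + config.spo2_bias, 0.0, 100.0)
                )
            raws.append(est.spo2)
        intervals.append(row)
    out: dict[str, Any] = {"intervals": intervals}
    if raws:
        out["mean_spo2_raw"] = float(np.mean(raws))
        if config.spo2_bias is not None:
            out["mean_spo2_corrected"] = float(
                np.mean([r["spo2_corrected"] for r in intervals if r["valid"]])
            )
    return out


def _temp_stage(log: DeviceLog, config: SessionConfig) -> dict | None:
    temp = log.temp()
    if temp is None:
        return None
    out: dict[str, Any] = {
        "t_s": temp.t.tolist(),
        "skin_c": temp.skin_c.tolist(),
        "mean_skin_c": float(temp.skin_c.mean()),
    }
    if config.temp_bias_c is not None:
        corrector = BiasCorrector()
        corrector.bias_ = config.temp_bias_c
        corrector.n_pairs_ = 0
        core = corrector.transform(temp.skin_c)
        out["core_est_c"] = core.tolist()
        out["mean_core_est_c"] = float(core.mean())
    return out


def _activity_stage(
    log: DeviceLog, config: SessionConfig, model: IntensityClassifier | None
) -> dict | None:
    accel = log.accel()
    if accel is None or model is None:
        return None
    step = int(round(config.activity_window_s * accel.fs_hz))
    n_windows = accel.x.size // step
    timeline = []
    for k in range(n_windows):
        sl = slice(k * step, (k + 1) * step)
        w = AccelWindow(
            t=accel.t[sl], x=accel.x[sl], y=accel.y[sl], z=accel.z[sl],
            fs_hz=accel.fs_hz,
        )
        timeline.append(
            {
                "window_start_s": float(accel.t[sl][0]),
                "window_end_s": float(accel.t[sl][0]) + config.activity_window_s,
                "level": classify(model, extract_features(w)),
            }
        )
    return {"timeline": timeline}


def _gsr_stage(log: DeviceLog, config: SessionConfig) -> dict | None:
    gsr = log.gsr()
    if gsr is None:
        return None
    delta = baseline_deviation(
        gsr,
        baseline_window_s=config.gsr_baseline_window_s,
        smooth_s=config.gsr_smooth_s,
    )
    return {
        "t_s": gsr.t.tolist(),
        "delta_us": delta.tolist(),
        "max_delta_us": float(delta.max()),
        "baseline_window_s": list(config.gsr_baseline_window_s),
    }


def analyze_session(
    log: DeviceLog,
    config: SessionConfig | None = None,
    activity_model: IntensityClassifier | None = None,
) -> SessionReport:
    """Run all analysis stages over one device log.

    Stages whose input stream or model is absent are simply omitted;
    stages that raise are recorded under ``report.errors`` and do not stop
    the others.
    """
    config = config or SessionConfig()
    report = SessionReport()
    stages = {
        "hr": lambda: _hr_stage(log, config),
        "spo2": lambda: _spo2_stage(log, config),
        "core_temp": lambda: _temp_stage(log, config),
        "activity": lambda: _activity_stage(log, config, activity_model),
        "gsr": lambda: _gsr_stage(log, config),
    }
    for name, stage in stages.items():
        try:
            setattr(report, name, stage())
        except Exception as exc:  # stage isolation: record and continue
            report.errors[name] = f"{type(exc).__name__}: {exc}"
    report.provenance = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "n_rows": int(log.df.shape[0]),
        "streams": {s: log.has_stream(s) for s in ("ppg", "accel", "temp", "gsr")},
        "activity_model": "supplied" if activity_model is not None else None,
    }
    return report
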