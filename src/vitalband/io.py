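"""Device-log CSV reading and writing.

A device log is the off-line dump of one wearing session: a single CSV
with a ``#``-prefixed header block declaring per-stream sampling rates,
then one row per timestamp with whichever sensor sampled at that instant.
Streams run at different rates (PPG 50 Hz, accelerometry 10 Hz,
temperature and GSR 1 Hz), so most cells are empty; missing values stay
explicit empty cells and are never filled.

Header block::

    # vitalband-log v1
    # fs_ppg_hz: 50.0
    # fs_accel_hz: 10.0
    # fs_temp_hz: 1.0
    # fs_gsr_hz: 1.0
    timestamp_s,red,ir,accel_x_mg,accel_y_mg,accel_z_mg,skin_temp_c,gsr_code
    ...
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DeviceLogError
from .types import AccelWindow, DualPPG, GSRSeries, TempSeries

__all__ = ["DeviceLog", "read_device_log", "write_device_log", "build_device_log"]

logger = logging.getLogger(__name__)

MAGIC = "vitalband-log v1"

COLUMNS = (
    "timestamp_s",
    "red",
    "ir",
    "accel_x_mg",
    "accel_y_mg",
    "accel_z_mg",
    "skin_temp_c",
    "gsr_code",
)

_STREAM_COLUMNS = {
    "ppg": ("red", "ir"),
    "accel": ("accel_x_mg", "accel_y_mg", "accel_z_mg"),
    "temp": ("skin_temp_c",),
    "gsr": ("gsr_code",),
}


@dataclass
class DeviceLog:
    """One session's multi-rate sensor rows plus declared sampling rates."""

    df: pd.DataFrame
    rates: dict[str, float] = field(default_factory=dict)

    def has_stream(self, stream: str) -> bool:
        cols = _STREAM_COLUMNS[stream]
        return all(c in self.df.columns for c in cols)

    def _stream_frame(self, stream: str) -> pd.DataFrame:
        cols = ["timestamp_s", *_STREAM_COLUMNS[stream]]
        return self.df[cols].dropna().reset_index(drop=True)

    def ppg(self) -> DualPPG | None:
        if not self.has_stream("ppg"):
            return None
        sf = self._stream_frame("ppg")
        if sf.empty:
            return None
        return DualPPG(
            t=sf["timestamp_s"].to_numpy(),
            red=sf["red"].to_numpy(),
            ir=sf["ir"].to_numpy(),
            fs_hz=self.rates.get("ppg", 50.0),
        )

    def accel(self) -> AccelWindow | None:
        if not self.has_stream("accel"):
            return None
        sf = self._stream_frame("accel")
        if sf.empty:
            return None
        return AccelWindow(
            t=sf["timestamp_s"].to_numpy(),
            x=sf["accel_x_mg"].to_numpy(),
            y=sf["accel_y_mg"].to_numpy(),
            z=sf["accel_z_mg"].to_numpy(),
            fs_hz=self.rates.get("accel", 10.0),
        )

    def temp(self) -> TempSeries | None:
        if not self.has_stream("temp"):
            return None
        sf = self._stream_frame("temp")
        if sf.empty:
            return None
        return TempSeries(
            t=sf["timestamp_s"].to_numpy(),
            skin_c=sf["skin_temp_c"].to_numpy(),
            fs_hz=self.rates.get("temp", 1.0),
        )

    def gsr(self) -> GSRSeries | None:
        if not self.has_stream("gsr"):
            return None
        sf = self._stream_frame("gsr")
        if sf.empty:
            return None
        return GSRSeries(
            t=sf["timestamp_s"].to_numpy(),
            code=sf["gsr_code"].to_numpy(),
            fs_hz=self.rates.get("gsr", 1.0),
        )


def build_device_log(
    ppg: DualPPG | None = None,
    accel: AccelWindow | list[AccelWindow] | None = None,
    temp: TempSeries | None = None,
    gsr: GSRSeries | None = None,
) -> DeviceLog:
    """Assemble a multi-rate log by outer-joining streams on timestamps.

    Timestamps are rounded to nanoseconds before joining so samples that
    coincide in time (e.g. every fifth PPG sample with an accelerometer
    sample) share a row.
    """
    frames: list[pd.DataFrame] = []
    rates: dict[str, float] = {}

    def add(t, cols: dict, stream: str, fs: float):
        frame = pd.DataFrame({"timestamp_s": np.round(t, 9), **cols})
        frames.append(frame)
        rates[stream] = fs

    if ppg is not None:
        add(ppg.t, {"red": ppg.red, "ir": ppg.ir}, "ppg", ppg.fs_hz)
    if accel is not None:
        windows = accel if isinstance(accel, list) else [accel]
        t = np.concatenate([w.t for w in windows])
        add(
            t,
            {
                "accel_x_mg": np.concatenate([w.x for w in windows]),
                "accel_y_mg": np.concatenate([w.y for w in windows]),
                "accel_z_mg": np.concatenate([w.z for w in windows]),
            },
            "accel",
            windows[0].fs_hz,
        )
    if temp is not None:
        add(temp.t, {"skin_temp_c": temp.skin_c}, "temp", temp.fs_hz)
    if gsr is not None:
        codes = gsr.code
        if codes is None:
            from .gsr import conductance_to_adc

            codes = conductance_to_adc(gsr.conductance_us)
        add(gsr.t, {"gsr_code": codes}, "gsr", gsr.fs_hz)
    if not frames:
        raise ValueError("at least one stream is required")

    merged = frames[0]
    for frame in frames[1:]:
        merged = merged.merge(frame, on="timestamp_s", how="outer")
    merged = merged.sort_values("timestamp_s", kind="stable").reset_index(drop=True)
    return DeviceLog(df=merged, rates=rates)


def write_device_log(log: DeviceLog, path: str | Path) -> None:
    """Write a device log with its ``#`` header block."""
    path = Path(path)
    buf = _io.StringIO()
    buf.write(f"# {MAGIC}\n")
    for stream in ("ppg", "accel", "temp", "gsr"):
        if stream in log.rates:
            buf.write(f"# fs_{stream}_hz: {log.rates[stream]!r}\n")
    log.df.to_csv(buf, index=False)
    path.write_text(buf.getvalue())


def read_device_log(path: str | Path) -> DeviceLog:
    """Read and validate a device-log CSV.

    Raises :class:`DeviceLogError` (with the 1-based line number where
    known) on an unknown column, a non-numeric cell, a row with the wrong
    field count, or non-monotone timestamps.  Streams whose columns are
    absent are loaded as unavailable, with a warning, so partial logs
    still analyze.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    rates: dict[str, float] = {}
    n_header = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_header += 1
        body = line.lstrip("#").strip()
        if ":" in body:
            key, _, value = body.partition(":")
            key = key.strip()
            if key.startswith("fs_") and key.endswith("_hz"):
                try:
                    rates[key[3:-3]] = float(value)
                except ValueError:
                    raise DeviceLogError(
                        f"malformed rate declaration {body!r}", line=n_header
                    ) from None
    if not lines[:n_header] or MAGIC not in lines[0]:
        raise DeviceLogError(f"not a device log (missing '# {MAGIC}' header)", line=1)
    data_text = "\n".join(lines[n_header:])

    try:
        df = pd.read_csv(_io.StringIO(data_text), dtype=str, on_bad_lines="error")
    except pd.errors.ParserError as exc:
        raise DeviceLogError(f"malformed CSV: {exc}") from exc

    unknown = [c for c in df.columns if c not in COLUMNS]
    if unknown:
        raise DeviceLogError(f"unknown column(s) {unknown}")
    if "timestamp_s" not in df.columns:
        raise DeviceLogError("missing timestamp_s column")

    # data row i sits at file line n_header + 2 + i (1-based, after header row)
    for col in df.columns:
        raw = df[col]
        numeric = pd.to_numeric(raw, errors="coerce")
        bad = numeric.isna() & raw.notna() & (raw.str.strip() != "")
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise DeviceLogError(
                f"non-numeric value {raw.iloc[i]!r} in column {col!r}",
                line=n_header + 2 + i,
            )
        # numpy's parser is round-trip exact; pandas' fast path is not
        df[col] = raw.astype(float)
    if df["timestamp_s"].isna().any():
        i = int(np.flatnonzero(df["timestamp_s"].isna().to_numpy())[0])
        raise DeviceLogError("missing timestamp", line=n_header + 2 + i)
    ts = df["timestamp_s"].to_numpy()
    if np.any(np.diff(ts) < 0):
        i = int(np.flatnonzero(np.diff(ts) < 0)[0]) + 1
        raise DeviceLogError("timestamps are not monotone non-decreasing",
                             line=n_header + 2 + i)

    log = DeviceLog(df=df, rates=rates)
    for stream, cols in _STREAM_COLUMNS.items():
        if not all(c in df.columns for c in cols):
            logger.warning(
                "device log %s has no %s column(s) %s; %s analyses disabled",
                path.name, stream, cols, stream,
            )
    return log
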