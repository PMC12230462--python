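"""Data containers and file IO.

Every 1-D assay (Ca2+ transients, cell shortening, fluorometry, O2,
pressure-volume) travels as a :class:`Trace` — a uniformly sampled time
series plus a table of labeled events (stimuli or reagent additions).
Line-scan images, RGB micrographs, PV series and qPCR tables have their
own containers.  On-disk formats are plain text (CSV + sidecar JSON)
except images, which are TIFF/PNG.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Event",
    "Trace",
    "LineScan",
    "PvSeries",
    "read_trace",
    "write_trace",
    "read_linescan",
    "write_linescan",
    "read_pv_series",
    "write_pv_series",
    "read_qpcr_table",
    "write_qpcr_table",
    "write_ground_truth",
    "read_ground_truth",
]

_UNIFORMITY_RTOL = 1e-9


@dataclass(frozen=True)
class Event:
    """A labeled instant on a trace: a pacing stimulus or a reagent addition."""

    time: float
    label: str
    amount: float | None = None


@dataclass
class Trace:
    """Uniformly sampled time series with labeled events.

    Parameters
    ----------
    time
        Sample times, strictly increasing, uniform spacing (ms for cell
        signals, s for fluorometry/respirometry).
    value
        Signal: fluorescence (a.u.), cell length (um), O2 concentration...
    events
        Stimulus / addition annotations, time-ordered.
    """

    time: np.ndarray
    value: np.ndarray
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValueError("trace needs at least 2 samples")
        if self.value.shape != self.time.shape:
            raise ValueError("time and value must have equal length")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=_UNIFORMITY_RTOL, atol=0):
            raise ValueError("sampling interval must be constant")
        self.events = sorted(self.events, key=lambda e: e.time)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def event_times(self, label: str | None = None) -> np.ndarray:
        ev = self.events if label is None else [e for e in self.events if e.label == label]
        return np.array([e.time for e in ev], dtype=float)

    def index_at(self, t: float) -> int:
        """Index of the first sample at or after time ``t``."""
        return int(np.searchsorted(self.time, t - 1e-12 * max(1.0, abs(t))))


@dataclass
class LineScan:
    """Confocal line-scan record: fluorescence on a space x time grid.

    ``intensity[i, j]`` is the fluorescence at spatial pixel ``i`` (pitch
    ``pixel_um``, the recordings emulated use 0.1 um) and scan line ``j``
    (period ``line_period_ms``).
    """

    intensity: np.ndarray
    pixel_um: float
    line_period_ms: float
    cell_extent_um: float | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2 or self.intensity.size == 0:
            raise ValueError("intensity must be a non-empty 2-D array")
        if self.pixel_um <= 0 or self.line_period_ms <= 0:
            raise ValueError("pixel_um and line_period_ms must be positive")
        if self.cell_extent_um is None:
            self.cell_extent_um = self.intensity.shape[0] * self.pixel_um
        elif self.cell_extent_um > self.intensity.shape[0] * self.pixel_um + 1e-9:
            raise ValueError("cell_extent_um exceeds the scanned length")

    @property
    def n_space(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_lines(self) -> int:
        return self.intensity.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_lines * self.line_period_ms / 1000.0


@dataclass
class PvSeries:
    """Left-ventricular pressure-volume time series (time ms, P mmHg, V uL)."""

    time: np.ndarray
    pressure: np.ndarray
    volume: np.ndarray
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        if not (self.time.shape == self.pressure.shape == self.volume.shape):
            raise ValueError("time, pressure and volume must have equal length")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=_UNIFORMITY_RTOL, atol=0):
            raise ValueError("sampling interval must be constant")
        if np.any(self.volume <= 0):
            raise ValueError("volume must be positive")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


# ---------------------------------------------------------------------------
# CSV / JSON round-trips
# ---------------------------------------------------------------------------

def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a trace as ``<path>`` CSV plus ``<stem>.events.csv`` sidecar."""
    path = Path(path)
    pd.DataFrame({"time": trace.time, "value": trace.value}).to_csv(path, index=False)
    ev = pd.DataFrame(
        [(e.time, e.label, e.amount) for e in trace.events],
        columns=["time", "label", "amount"],
    )
    ev.to_csv(path.with_suffix(".events.csv"), index=False)


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    df = pd.read_csv(path)
    events: list[Event] = []
    sidecar = path.with_suffix(".events.csv")
    if sidecar.exists():
        ev = pd.read_csv(sidecar)
        for _, row in ev.iterrows():
            amount = row.get("amount")
            events.append(
                Event(float(row["time"]), str(row["label"]),
                      None if pd.isna(amount) else float(amount))
            )
    return Trace(df["time"].to_numpy(), df["value"].to_numpy(), events)


def write_linescan(scan: LineScan, path: str | Path) -> None:
    """Write a 16-bit grayscale TIFF plus a JSON metadata sidecar."""
    import tifffile

    path = Path(path)
    img = scan.intensity
    if img.min() < 0 or img.max() > 65535:
        raise ValueError("intensity out of 16-bit range; rescale before writing")
    tifffile.imwrite(path, np.round(img).astype(np.uint16))
    meta = {
        "pixel_um": scan.pixel_um,
        "line_period_ms": scan.line_period_ms,
        "cell_extent_um": scan.cell_extent_um,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_linescan(path: str | Path) -> LineScan:
    import tifffile

    path = Path(path)
    img = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return LineScan(img.astype(float), meta["pixel_um"], meta["line_period_ms"],
                    meta.get("cell_extent_um"))


def write_pv_series(series: PvSeries, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(
        {"time": series.time, "pressure_mmHg": series.pressure,
         "volume_uL": series.volume}
    ).to_csv(path, index=False)
    ev = pd.DataFrame(
        [(e.time, e.label, e.amount) for e in series.events],
        columns=["time", "label", "amount"],
    )
    ev.to_csv(path.with_suffix(".events.csv"), index=False)


def read_pv_series(path: str | Path) -> PvSeries:
    path = Path(path)
    df = pd.read_csv(path)
    events: list[Event] = []
    sidecar = path.with_suffix(".events.csv")
    if sidecar.exists():
        ev = pd.read_csv(sidecar)
        for _, row in ev.iterrows():
            amount = row.get("amount")
            events.append(
                Event(float(row["time"]), str(row["label"]),
                      None if pd.isna(amount) else float(amount))
            )
    return PvSeries(df["time"].to_numpy(), df["pressure_mmHg"].to_numpy(),
                    df["volume_uL"].to_numpy(), events)


def write_qpcr_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample", "group", "gene", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    return df


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_ground_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonify(truth), indent=2))


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
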