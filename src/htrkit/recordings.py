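"""Data model and file I/O for magnetometer/piezo recordings and events.

A recording session is one or two voltage channels sampled uniformly
(nominally 1000 Hz): a magnetometer coil channel carrying head-movement
dynamics, and optionally a piezoelectric pressure channel used to flag
jumping artifacts.  On disk a recording is either a CSV with columns
``time_s,coil_v[,piezo_v]`` or a 1-/2-channel float WAV.  Detected events
and reference annotations round-trip through small CSV formats, and the
detector configuration mirrors a flat JSON object.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

__all__ = [
    "TimeSeries",
    "DualChannelRecording",
    "DetectionConfig",
    "HtrEvent",
    "EventList",
    "AnnotationSet",
    "ClippingReport",
    "read_recording",
    "write_recording",
    "write_events",
    "read_events",
    "read_annotations",
    "write_annotations",
    "check_clipping",
]

#: Event classes understood by annotation files and the simulator.
EVENT_CLASSES = ("htr", "groom", "jump", "locomotor", "other")

#: Relative jitter tolerated in a CSV time column before it is declared
#: irregularly sampled.
_TIME_JITTER_TOL = 1e-6


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled voltage trace.

    Parameters
    ----------
    samples
        Voltage values in (amplified) volts.
    sample_rate
        Sampling rate in Hz, strictly positive.
    t0
        Time of the first sample, seconds from recording start.
    label
        Channel name, e.g. ``"coil"`` or ``"piezo"``.
    """

    samples: np.ndarray
    sample_rate: float
    t0: float = 0.0
    label: str = "coil"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.sample_rate <= 0:
            raise ParameterError(f"sample_rate must be > 0, got {self.sample_rate}")
        if samples.ndim != 1:
            raise ParameterError("TimeSeries samples must be one-dimensional")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ParameterError(f"channel {self.label!r} contains non-finite samples")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace duration in seconds (n_samples / sample_rate)."""
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        """Timestamps at sample centers: ``t0 + i / sample_rate``."""
        return self.t0 + np.arange(self.samples.size) / self.sample_rate

    def with_samples(self, samples: np.ndarray, label: str | None = None) -> "TimeSeries":
        """Copy of this trace carrying new sample values on the same grid."""
        return TimeSeries(samples, self.sample_rate, self.t0,
                          self.label if label is None else label)


@dataclass(frozen=True)
class DualChannelRecording:
    """A coil trace plus an optional co-recorded piezo trace."""

    coil: TimeSeries
    piezo: TimeSeries | None = None

    def __post_init__(self) -> None:
        if self.piezo is not None:
            if self.piezo.sample_rate != self.coil.sample_rate:
                raise ParameterError("coil and piezo must share sample_rate")
            if self.piezo.t0 != self.coil.t0:
                raise ParameterError("coil and piezo must share t0")

    @property
    def has_piezo(self) -> bool:
        return self.piezo is not None


@dataclass(frozen=True)
class DetectionConfig:
    """All constants of the conditional HTR detector.

    Defaults reproduce the published detector: 70-110 Hz Butterworth
    band-pass (order 3, applied zero-phase), prominence threshold
    min(15 x SD of the band-passed signal, 0.075 V), minimum event
    separation 200 ms, maximum width 90 ms at half prominence, piezo jump
    threshold 0.3 V with a +/-0.1 s timestamp matching window.
    """

    band_low_hz: float = 70.0
    band_high_hz: float = 110.0
    filter_order: int = 3
    sd_multiplier: float = 15.0
    prominence_cap_v: float = 0.075
    min_separation_s: float = 0.200
    max_width_s: float = 0.090
    piezo_threshold_v: float = 0.3
    piezo_match_tol_s: float = 0.1
    edge_guard_s: float = 0.25
    clip_limit_v: float = 2.5
    # non-default behavioural switches (see detector / jump_filter docs)
    robust_sd: bool = False
    piezo_sd_multiplier: float | None = None
    piezo_min_separation_s: float = 0.100
    piezo_baseline_window_s: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.band_low_hz < self.band_high_hz):
            raise ParameterError(
                f"need 0 < band_low_hz < band_high_hz, got "
                f"({self.band_low_hz}, {self.band_high_hz})")
        if self.filter_order < 1:
            raise ParameterError("filter_order must be >= 1")
        positive = ("sd_multiplier", "prominence_cap_v", "min_separation_s",
                    "max_width_s", "piezo_threshold_v", "piezo_match_tol_s",
                    "clip_limit_v", "piezo_min_separation_s",
                    "piezo_baseline_window_s")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        if self.edge_guard_s < 0:
            raise ParameterError("edge_guard_s must be >= 0")

    @classmethod
    def from_json(cls, path: str | Path) -> "DetectionConfig":
        """Load a config from a flat JSON object.

        Keys mirror the field names exactly; unspecified keys take their
        defaults; unknown keys are rejected so typos cannot silently fall
        back to defaults.
        """
        with open(path) as fh:
            try:
                raw = json.load(fh)
            except json.JSONDecodeError as exc:
                raise FormatError(f"invalid JSON config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise FormatError(f"config {path} must be a JSON object")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")

    def digest(self) -> str:
        """Stable hash of the config, used in event-list provenance."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


#: Reasons an event may be flagged as excluded.
EXCLUSION_REASONS = ("none", "jump_match")


@dataclass(frozen=True)
class HtrEvent:
    """One detected head-twitch event.

    ``timestamp`` is the envelope-peak apex in seconds from recording
    start; ``prominence`` is topographic peak prominence in volts; ``width``
    is the peak width in seconds measured at half prominence.  Excluded
    events are retained for audit, never deleted.
    """

    timestamp: float
    prominence: float
    width: float
    excluded: bool = False
    exclusion_reason: str = "none"

    def __post_init__(self) -> None:
        if self.prominence <= 0:
            raise ParameterError("event prominence must be > 0")
        if self.width <= 0:
            raise ParameterError("event width must be > 0")
        if self.exclusion_reason not in EXCLUSION_REASONS:
            raise ParameterError(
                f"exclusion_reason must be one of {EXCLUSION_REASONS}")
        if self.excluded != (self.exclusion_reason != "none"):
            raise ParameterError("excluded flag inconsistent with reason")


@dataclass
class EventList:
    """Chronologically ordered detected events with provenance metadata."""

    events: list[HtrEvent] = field(default_factory=list)
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.timestamp)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[HtrEvent]:
        return iter(self.events)

    def accepted(self) -> list[HtrEvent]:
        """Events that survived all exclusion filters."""
        return [e for e in self.events if not e.excluded]

    def accepted_timestamps(self) -> np.ndarray:
        return np.array([e.timestamp for e in self.accepted()], dtype=float)


@dataclass
class AnnotationSet:
    """Reference annotations: (timestamp, behavioral class) records."""

    timestamps: np.ndarray
    classes: list[str]

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        if ts.size != len(self.classes):
            raise ParameterError("timestamps and classes differ in length")
        order = np.argsort(ts, kind="stable")
        self.timestamps = ts[order]
        self.classes = [self.classes[i] for i in order]
        for cls in self.classes:
            if cls not in EVENT_CLASSES:
                raise ParameterError(f"unknown annotation class {cls!r}")

    def __len__(self) -> int:
        return self.timestamps.size

    def of_class(self, cls: str) -> np.ndarray:
        """Timestamps of all annotations of one class."""
        mask = np.array([c == cls for c in self.classes], dtype=bool)
        return self.timestamps[mask]


@dataclass(frozen=True)
class ClippingReport:
    """Advisory report on samples at or beyond the clip limit."""

    count: int
    timestamps: np.ndarray
    limit_v: float

    @property
    def clipped(self) -> bool:
        return self.count > 0


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _infer_rate_from_times(times: np.ndarray, path: str | Path) -> float:
    if times.size < 2:
        raise FormatError(f"{path}: need at least 2 samples to infer sample rate")
    dt = np.diff(times)
    if np.any(dt <= 0):
        raise FormatError(f"{path}: time column is not strictly increasing")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > _TIME_JITTER_TOL * max(med, 1.0) + 1e-12:
        raise FormatError(
            f"{path}: irregular sampling (time-step jitter exceeds "
            f"{_TIME_JITTER_TOL:g} relative tolerance)")
    return 1.0 / med


def read_recording(path: str | Path, format: str | None = None) -> DualChannelRecording:
    """Read a one- or two-channel recording from CSV or WAV.

    CSV must have header ``time_s,coil_v`` or ``time_s,coil_v,piezo_v``;
    the sample rate is inferred from the median time step and the time
    column must be uniform to within 1 ppm.  WAV must be 1- or 2-channel;
    integer PCM is rescaled to [-1, 1) floats.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format is None:
        format = "wav" if path.suffix.lower() == ".wav" else "csv"
    if format not in ("csv", "wav"):
        raise ParameterError(f"format must be 'csv' or 'wav', got {format!r}")
    if format == "wav":
        return _read_wav(path)
    return _read_csv(path)


def _read_csv(path: Path) -> DualChannelRecording:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    cols = list(df.columns)
    if cols[:2] != ["time_s", "coil_v"] or len(cols) > 3 or (
            len(cols) == 3 and cols[2] != "piezo_v"):
        raise FormatError(
            f"{path}: expected header 'time_s,coil_v[,piezo_v]', got {cols}")
    if len(df) == 0:
        raise FormatError(f"{path}: no data rows")
    times = df["time_s"].to_numpy(dtype=float)
    rate = _infer_rate_from_times(times, path)
    t0 = float(times[0])
    coil = TimeSeries(df["coil_v"].to_numpy(dtype=float), rate, t0, "coil")
    piezo = None
    if "piezo_v" in df.columns:
        piezo = TimeSeries(df["piezo_v"].to_numpy(dtype=float), rate, t0, "piezo")
    return DualChannelRecording(coil, piezo)


def _read_wav(path: Path) -> DualChannelRecording:
    from scipy.io import wavfile

    try:
        rate, data = wavfile.read(path)
    except ValueError as exc:
        raise FormatError(f"{path}: unreadable WAV ({exc})") from exc
    if data.size == 0:
        raise FormatError(f"{path}: empty WAV")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    if data.ndim == 1:
        data = data[:, None]
    if data.shape[1] > 2:
        raise FormatError(f"{path}: expected 1 or 2 channels, got {data.shape[1]}")
    coil = TimeSeries(data[:, 0], float(rate), 0.0, "coil")
    piezo = (TimeSeries(data[:, 1], float(rate), 0.0, "piezo")
             if data.shape[1] == 2 else None)
    return DualChannelRecording(coil, piezo)


def write_recording(rec: DualChannelRecording, path: str | Path,
                    format: str | None = None) -> None:
    """Write a recording as CSV (``time_s,coil_v[,piezo_v]``) or float WAV."""
    path = Path(path)
    if format is None:
        format = "wav" if path.suffix.lower() == ".wav" else "csv"
    if format == "wav":
        from scipy.io import wavfile

        if rec.piezo is not None:
            data = np.column_stack([rec.coil.samples, rec.piezo.samples])
        else:
            data = rec.coil.samples
        wavfile.write(path, int(round(rec.coil.sample_rate)),
                      data.astype(np.float32))
        return
    cols = {"time_s": rec.coil.times, "coil_v": rec.coil.samples}
    if rec.piezo is not None:
        cols["piezo_v"] = rec.piezo.samples
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")


_EVENT_COLUMNS = ["timestamp_s", "prominence_v", "width_ms", "excluded", "reason"]


def write_events(events: EventList, path: str | Path) -> None:
    """Write events as CSV: ``timestamp_s,prominence_v,width_ms,excluded,reason``.

    The textual fields round-trip bit-exactly through :func:`read_events`.
    """
    rows = [
        {
            "timestamp_s": f"{e.timestamp:.3f}",
            "prominence_v": f"{e.prominence:.6f}",
            "width_ms": f"{e.width * 1e3:.1f}",
            "excluded": "true" if e.excluded else "false",
            "reason": e.exclusion_reason,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(path, index=False)


def read_events(path: str | Path) -> EventList:
    """Read an event CSV produced by :func:`write_events`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if list(df.columns) != _EVENT_COLUMNS:
        raise FormatError(f"{path}: expected columns {_EVENT_COLUMNS}")
    events = [
        HtrEvent(
            timestamp=float(row.timestamp_s),
            prominence=float(row.prominence_v),
            width=float(row.width_ms) / 1e3,
            excluded=row.excluded == "true",
            exclusion_reason=row.reason,
        )
        for row in df.itertuples()
    ]
    return EventList(events, source={"path": str(path)})


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read reference annotations from CSV ``timestamp_s,class``."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if list(df.columns) != ["timestamp_s", "class"]:
        raise FormatError(f"{path}: expected columns ['timestamp_s', 'class']")
    return AnnotationSet(df["timestamp_s"].to_numpy(dtype=float),
                         [str(c) for c in df["class"]])


def write_annotations(annotations: AnnotationSet, path: str | Path) -> None:
    pd.DataFrame({
        "timestamp_s": [f"{t:.3f}" for t in annotations.timestamps],
        "class": annotations.classes,
    }).to_csv(path, index=False)


def check_clipping(ts: TimeSeries, limit_v: float = 2.5) -> ClippingReport:
    """Report samples with ``|v| >= limit_v``.

    Clipping against the +/-2.5 V acquisition range distorts wavelet shape
    and biases prominence, so it is worth flagging, but it is advisory: a
    warning is emitted and detection proceeds.
    """
    if limit_v <= 0:
        raise ParameterError("limit_v must be > 0")
    mask = np.abs(ts.samples) >= limit_v
    count = int(mask.sum())
    report = ClippingReport(count, ts.times[mask], limit_v)
    if count:
        warnings.warn(
            f"channel {ts.label!r}: {count} sample(s) at or beyond "
            f"+/-{limit_v} V; signal may be clipped", stacklevel=2)
    return report


def events_from_timestamps(timestamps: Sequence[float],
                           prominence: float = 0.1,
                           width: float = 0.03) -> EventList:
    """Build a plain EventList from bare timestamps (testing/interop helper)."""
    return EventList([HtrEvent(float(t), prominence, width) for t in timestamps])
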