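"""Jump-artifact exclusion using the piezoelectric pressure channel.

Jumps produce broadband coil wavelets that can masquerade as head twitches,
but they also slam the floor-mounted piezo sensor.  The filter annotates
piezo maxima above an absolute 0.3 V threshold (about 8 standard deviations
of the piezo baseline on the reference hardware) and excludes any detected
event whose timestamp falls within +/-0.1 s of an annotated maximum.
Excluded events are flagged, never deleted, so the audit trail survives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ChannelError, ParameterError
from .recordings import DetectionConfig, EventList, HtrEvent, TimeSeries

__all__ = ["PiezoMaxima", "annotate_piezo_maxima", "exclude_jumps"]


@dataclass(frozen=True)
class PiezoMaxima:
    """Annotated suprathreshold maxima of the piezo channel."""

    timestamps: np.ndarray
    peak_values: np.ndarray
    threshold_v: float

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        pv = np.asarray(self.peak_values, dtype=float)
        if ts.size != pv.size:
            raise ParameterError("timestamps and peak_values differ in length")
        if np.any(np.diff(ts) < 0):
            raise ParameterError("piezo maxima timestamps must be sorted")
        if pv.size and np.any(pv < self.threshold_v):
            raise ParameterError("peak below annotation threshold")
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "peak_values", pv)

    def __len__(self) -> int:
        return self.timestamps.size


def _rolling_median_baseline(x: np.ndarray, window: int) -> np.ndarray:
    # centered rolling median; robust to the spikes we are trying to keep
    return (pd.Series(x)
            .rolling(window, center=True, min_periods=1)
            .median()
            .to_numpy())


def annotate_piezo_maxima(piezo: TimeSeries | None,
                          cfg: DetectionConfig | None = None) -> PiezoMaxima:
    """Annotate piezo maxima exceeding the jump threshold.

    Pipeline: subtract a centered 1 s rolling-median baseline, rectify,
    then pick local maxima at or above the threshold separated by at least
    100 ms, so the ringing of a single takeoff or landing yields one
    annotation rather than dozens.

    The threshold is the absolute ``piezo_threshold_v`` (default 0.3 V);
    setting ``piezo_sd_multiplier`` switches to a multiple of the
    baseline-corrected signal's SD for hardware with a different
    noise floor.
    """
    if cfg is None:
        cfg = DetectionConfig()
    if piezo is None:
        raise ChannelError("recording has no piezo channel")
    window = max(1, int(round(cfg.piezo_baseline_window_s * piezo.sample_rate)))
    corrected = piezo.samples - _rolling_median_baseline(piezo.samples, window)
    rectified = np.abs(corrected)
    if cfg.piezo_sd_multiplier is not None:
        threshold = cfg.piezo_sd_multiplier * float(np.std(corrected))
    else:
        threshold = cfg.piezo_threshold_v
    distance = max(1, int(round(cfg.piezo_min_separation_s * piezo.sample_rate)))
    peaks, props = sps.find_peaks(rectified, height=threshold,
                                  distance=distance)
    timestamps = piezo.t0 + peaks / piezo.sample_rate
    return PiezoMaxima(timestamps=timestamps,
                       peak_values=props.get("peak_heights",
                                             np.empty(0, dtype=float)),
                       threshold_v=threshold)


def exclude_jumps(events: EventList, maxima: PiezoMaxima,
                  tol_s: float = 0.1) -> EventList:
    """Flag events within ``tol_s`` of any piezo maximum as jump artifacts.

    Matching is interval membership (event-to-any-maximum, not one-to-one):
    a single jump may shield several spurious detections.  Already-excluded
    events keep their flag.
    """
    if tol_s <= 0:
        raise ParameterError("tol_s must be > 0")
    mx = maxima.timestamps
    out: list[HtrEvent] = []
    for ev in events:
        matched = bool(mx.size) and bool(
            np.min(np.abs(mx - ev.timestamp)) <= tol_s)
        if matched and not ev.excluded:
            out.append(HtrEvent(ev.timestamp, ev.prominence, ev.width,
                                excluded=True, exclusion_reason="jump_match"))
        else:
            out.append(ev)
    source = dict(events.source)
    source["jump_filter"] = {"tol_s": tol_s, "n_maxima": len(maxima),
                             "n_excluded": sum(e.excluded for e in out)}
    return EventList(out, source=source)
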