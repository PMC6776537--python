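"""Conditional head-twitch event detection on the coil channel.

The detector tests each unipolar envelope peak against three criteria:

(i)   peak prominence at or above the session threshold
      min(15 x SD of the 70-110 Hz band-passed signal, 0.075 V),
(ii)  separation of at least 200 ms from any other accepted event,
(iii) width below 90 ms measured at half the prominence.

Prominence is topographic (height above the highest saddle to any larger
peak), width crossings are found by linear interpolation at evaluation
height ``peak - prominence/2``.  The separation rule is enforced greedily
in descending prominence order, ties broken by earlier timestamp, so
detection is deterministic and favors the strongest events.  Events within
an edge guard (default 250 ms) of either end of the trace are dropped to
avoid filter-transient artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .dsp import Envelope, bandpass, envelope_double_maxima, rectify
from .errors import DegenerateSignalError, ParameterError
from .recordings import DetectionConfig, EventList, HtrEvent, TimeSeries

__all__ = [
    "ThresholdInfo",
    "CandidatePeak",
    "compute_threshold",
    "find_candidate_peaks",
    "detect_htr",
]


@dataclass(frozen=True)
class ThresholdInfo:
    """Effective prominence threshold for one analyzed epoch."""

    sd_v: float
    threshold_v: float
    capped: bool

    def __post_init__(self) -> None:
        if self.sd_v < 0 or self.threshold_v <= 0:
            raise ParameterError("threshold quantities must be positive")


@dataclass(frozen=True)
class CandidatePeak:
    """An envelope local maximum passing the prominence criterion."""

    index: int
    timestamp: float
    prominence: float
    width: float


def compute_threshold(bandpassed: TimeSeries,
                      cfg: DetectionConfig) -> ThresholdInfo:
    """Session prominence threshold from the band-passed (signed) signal.

    The SD is taken over the full analyzed epoch of the signed band-passed
    trace, not the envelope.  ``robust_sd`` switches to the scaled median
    absolute deviation (1.4826 x MAD), which resists inflation by dense
    event trains; it is off by default to match the published detector.
    A zero-variance signal is refused: a zero threshold would accept every
    ripple and indicates a dead or disconnected channel.
    """
    x = bandpassed.samples
    if x.size == 0:
        raise ParameterError("cannot compute threshold of empty signal")
    if cfg.robust_sd:
        sd = 1.4826 * float(np.median(np.abs(x - np.median(x))))
    else:
        sd = float(np.std(x))
    if sd == 0.0:
        raise DegenerateSignalError(
            "band-passed signal has zero variance; refusing zero threshold")
    raw = cfg.sd_multiplier * sd
    capped = raw > cfg.prominence_cap_v
    return ThresholdInfo(sd_v=sd,
                         threshold_v=min(raw, cfg.prominence_cap_v),
                         capped=capped)


def find_candidate_peaks(env: Envelope,
                         threshold_v: float) -> list[CandidatePeak]:
    """Envelope local maxima with topographic prominence >= threshold.

    Width is measured at evaluation height ``peak - prominence/2`` with
    linearly interpolated crossings.  An empty list is a valid result.
    """
    if threshold_v <= 0:
        raise ParameterError("threshold_v must be > 0")
    y = env.samples
    peaks, props = sps.find_peaks(y, prominence=threshold_v)
    if peaks.size == 0:
        return []
    widths, _, _, _ = sps.peak_widths(
        y, peaks, rel_height=0.5,
        prominence_data=(props["prominences"],
                         props["left_bases"], props["right_bases"]))
    fs = env.sample_rate
    return [
        CandidatePeak(index=int(p),
                      timestamp=env.t0 + int(p) / fs,
                      prominence=float(prom),
                      width=float(w) / fs)
        for p, prom, w in zip(peaks, props["prominences"], widths)
    ]


def _enforce_separation(candidates: list[CandidatePeak],
                        min_separation_s: float) -> list[CandidatePeak]:
    """Greedy acceptance in descending prominence, earlier time on ties."""
    order = sorted(candidates, key=lambda c: (-c.prominence, c.timestamp))
    accepted: list[CandidatePeak] = []
    for cand in order:
        if all(abs(cand.timestamp - a.timestamp) >= min_separation_s
               for a in accepted):
            accepted.append(cand)
    return sorted(accepted, key=lambda c: c.timestamp)


def detect_htr(coil: TimeSeries,
               cfg: DetectionConfig | None = None
               ) -> tuple[EventList, ThresholdInfo]:
    """Full detection pipeline on a coil trace.

    band-pass -> rectify -> double local-maxima envelope -> session
    threshold -> prominence candidates -> width rejection (>= 90 ms) ->
    greedy separation (200 ms) -> edge guard.  Returns the chronologically
    sorted accepted events together with the threshold actually applied.
    """
    if cfg is None:
        cfg = DetectionConfig()
    if coil.duration <= 2 * cfg.edge_guard_s:
        raise ParameterError(
            f"recording ({coil.duration:.3f} s) shorter than twice the "
            f"edge guard ({cfg.edge_guard_s} s)")
    bp = bandpass(coil, cfg.band_low_hz, cfg.band_high_hz, cfg.filter_order)
    threshold = compute_threshold(bp, cfg)
    env = envelope_double_maxima(rectify(bp),
                                 band=(cfg.band_low_hz, cfg.band_high_hz))
    candidates = find_candidate_peaks(env, threshold.threshold_v)
    candidates = [c for c in candidates if c.width < cfg.max_width_s]
    candidates = _enforce_separation(candidates, cfg.min_separation_s)
    t_lo = coil.t0 + cfg.edge_guard_s
    t_hi = coil.t0 + coil.duration - cfg.edge_guard_s
    candidates = [c for c in candidates if t_lo <= c.timestamp <= t_hi]
    events = EventList(
        [HtrEvent(c.timestamp, c.prominence, c.width) for c in candidates],
        source={"config": cfg.digest(),
                "threshold_v": threshold.threshold_v,
                "capped": threshold.capped},
    )
    return events, threshold
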