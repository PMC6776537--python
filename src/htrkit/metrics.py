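"""Event-level validation of detections against reference annotations.

Detections and reference events (e.g. video-scored head twitches) are
matched one-to-one by timestamp within a tolerance; the resulting confusion
counts give the standard event-level rates: positive predictive value
PPV = TP/(TP+FP), false discovery rate FDR = FP/(TP+FP), and false
negative rate FNR = FN/(TP+FN).

A second, distinct statistic — :func:`event_class_fp_rate` — asks the
converse question for artifact classes: what fraction of reference events
of a given class (e.g. jumps) attracted at least one accepted detection.
Its denominator is the reference class size, not the detection count, so
it is not an FDR and is named accordingly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .recordings import AnnotationSet, EventList

__all__ = [
    "MatchResult",
    "RateSummary",
    "match_events",
    "compute_rates",
    "event_class_fp_rate",
]

#: Default tolerance for comparing detections with human video annotations.
HUMAN_MATCH_TOL_S = 0.5
#: Tolerance for sensor-to-sensor timestamp comparisons.
SENSOR_MATCH_TOL_S = 0.1


@dataclass(frozen=True)
class MatchResult:
    """One-to-one timestamp matching outcome."""

    tp: int
    fp: int
    fn: int
    pairs: tuple[tuple[float, float], ...]
    tol_s: float

    def __post_init__(self) -> None:
        if self.tp != len(self.pairs):
            raise ParameterError("tp must equal number of matched pairs")


@dataclass(frozen=True)
class RateSummary:
    """PPV / FDR / FNR with explicit undefined flags.

    A rate whose denominator is zero is NaN and flagged via the
    corresponding ``*_defined`` property rather than raising.
    """

    ppv: float
    fdr: float
    fnr: float
    n_reference: int
    n_detected: int

    @property
    def ppv_defined(self) -> bool:
        return not math.isnan(self.ppv)

    @property
    def fdr_defined(self) -> bool:
        return not math.isnan(self.fdr)

    @property
    def fnr_defined(self) -> bool:
        return not math.isnan(self.fnr)


def _detected_times(detected: EventList | np.ndarray) -> np.ndarray:
    if isinstance(detected, EventList):
        return detected.accepted_timestamps()
    return np.asarray(detected, dtype=float)


def match_events(detected: EventList, reference: AnnotationSet,
                 tol_s: float = HUMAN_MATCH_TOL_S,
                 cls: str = "htr") -> MatchResult:
    """Greedy one-to-one matching of accepted detections to reference events.

    All detection-reference pairs with ``|dt| <= tol_s`` are considered in
    ascending ``|dt|``; a pair is accepted iff neither member is already
    matched.  Unmatched detections count as false positives, unmatched
    reference events of the requested class as false negatives.  At typical
    event densities this greedy rule coincides with the minimum-total-|dt|
    assignment while staying deterministic and O(k log k).
    """
    if tol_s <= 0:
        raise ParameterError("tol_s must be > 0")
    det = _detected_times(detected)
    ref = reference.of_class(cls)
    candidates = []
    for i, td in enumerate(det):
        for j, tr in enumerate(ref):
            dt = abs(td - tr)
            if dt <= tol_s:
                candidates.append((dt, i, j))
    candidates.sort()
    used_det: set[int] = set()
    used_ref: set[int] = set()
    pairs: list[tuple[float, float]] = []
    for _, i, j in candidates:
        if i in used_det or j in used_ref:
            continue
        used_det.add(i)
        used_ref.add(j)
        pairs.append((float(det[i]), float(ref[j])))
    tp = len(pairs)
    result = MatchResult(tp=tp, fp=det.size - tp, fn=ref.size - tp,
                         pairs=tuple(sorted(pairs)), tol_s=tol_s)
    # conservation invariants, asserted on every run
    assert result.tp + result.fn == ref.size
    assert result.tp + result.fp == det.size
    return result


def compute_rates(m: MatchResult) -> RateSummary:
    """PPV/FDR/FNR from confusion counts; zero denominators yield NaN flags."""
    n_det = m.tp + m.fp
    n_ref = m.tp + m.fn
    ppv = m.tp / n_det if n_det else math.nan
    fdr = m.fp / n_det if n_det else math.nan
    fnr = m.fn / n_ref if n_ref else math.nan
    return RateSummary(ppv=ppv, fdr=fdr, fnr=fnr,
                       n_reference=n_ref, n_detected=n_det)


def event_class_fp_rate(detected: EventList, reference: AnnotationSet,
                        tol_s: float, cls: str) -> float:
    """Fraction of reference events of ``cls`` matched by >= 1 detection.

    Used for artifact classes: e.g. the fraction of visually identified
    jumping events that falsely triggered the detector.  Matching is
    membership (any accepted detection within tolerance), not one-to-one.
    """
    if tol_s <= 0:
        raise ParameterError("tol_s must be > 0")
    ref = reference.of_class(cls)
    if ref.size == 0:
        raise ParameterError(f"reference contains no events of class {cls!r}")
    det = _detected_times(detected)
    if det.size == 0:
        return 0.0
    hit = np.array([np.min(np.abs(det - tr)) <= tol_s for tr in ref])
    return float(hit.mean())
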