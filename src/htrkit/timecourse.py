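"""Drug-effect time-course analysis: binned counts, exponential decay,
half-life, and effect-concentration correlation.

After an acute dose the head-twitch count per 15 min bin decays roughly
exponentially, HTR(t) = HTR_0 * exp(-lambda * t).  The decay rate lambda
is extracted as minus the slope of an ordinary least-squares fit to the
natural log of the positive bin counts, and the effect half-life is
t_1/2 = ln 2 / lambda.  The same machinery fits tissue drug-concentration
series, and a Pearson correlation relates binned effect to concentration
at matched time points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, ParameterError
from .recordings import EventList

__all__ = [
    "BinnedCounts",
    "DecayFit",
    "bin_events",
    "fit_exponential_decay",
    "correlate_effect_concentration",
]


@dataclass(frozen=True)
class BinnedCounts:
    """Accepted-event counts in contiguous half-open time bins."""

    bin_width_s: float
    bin_start_times: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.bin_start_times, dtype=float)
        counts = np.asarray(self.counts, dtype=int)
        if starts.size != counts.size:
            raise ParameterError("bin starts and counts differ in length")
        if self.bin_width_s <= 0:
            raise ParameterError("bin_width_s must be > 0")
        if starts.size > 1 and not np.allclose(np.diff(starts),
                                               self.bin_width_s):
            raise ParameterError("bins must be contiguous")
        if np.any(counts < 0):
            raise ParameterError("counts must be nonnegative")
        object.__setattr__(self, "bin_start_times", starts)
        object.__setattr__(self, "counts", counts)

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def bin_centers_min(self) -> np.ndarray:
        return (self.bin_start_times + self.bin_width_s / 2) / 60.0


@dataclass(frozen=True)
class DecayFit:
    """Log-linear exponential-decay fit.

    ``lambda_`` is the decay rate in 1/min; ``half_life_min`` is
    ln2/lambda when lambda > 0 and NaN (flagged undefined) otherwise;
    ``r_squared`` refers to the log-linear regression.
    """

    lambda_: float
    half_life_min: float
    ln_intercept: float
    r_squared: float
    n_bins_used: int

    @property
    def half_life_defined(self) -> bool:
        return not math.isnan(self.half_life_min)


def bin_events(events: EventList, bin_width_s: float = 900.0,
               t_start: float = 0.0,
               t_end: float | None = None) -> BinnedCounts:
    """Count accepted events per half-open bin ``[t, t + w)``.

    A trailing partial bin is dropped, so the covered window is the largest
    whole-bin span inside ``[t_start, t_end)``.  Events exactly on a bin
    boundary belong to the later bin.
    """
    if bin_width_s <= 0:
        raise ParameterError("bin_width_s must be > 0")
    times = events.accepted_timestamps()
    if t_end is None:
        t_end = float(times.max()) + bin_width_s if times.size else bin_width_s
    if t_end <= t_start:
        raise ParameterError("t_end must exceed t_start")
    n_bins = int(np.floor((t_end - t_start) / bin_width_s))
    if n_bins < 1:
        raise ParameterError("window shorter than one bin")
    edges = t_start + bin_width_s * np.arange(n_bins + 1)
    counts, _ = np.histogram(times, bins=edges)
    # np.histogram closes the last bin on the right; re-impose half-open
    if times.size and np.any(times == edges[-1]):
        counts[-1] -= int(np.sum(times == edges[-1]))
    return BinnedCounts(bin_width_s=bin_width_s,
                        bin_start_times=edges[:-1], counts=counts)


def fit_exponential_decay(binned, times_min=None, *, start_index: int = 0,
                          zero_offset: float | None = None) -> DecayFit:
    """Fit ``y(t) = y0 * exp(-lambda * t)`` by OLS on ``(t, ln y)``.

    Accepts either a :class:`BinnedCounts` (times taken as bin starts,
    relative to ``start_index``, converted to minutes) or a plain value
    array with explicit ``times_min`` — the latter form serves
    concentration series.

    Zero values are excluded from the regression by default; passing
    ``zero_offset`` (e.g. 0.5) instead adds a continuity offset to every
    value before taking logs.  At least 3 strictly positive values must
    remain.  A non-positive fitted decay rate (growth or flat) yields
    ``lambda_ <= 0`` with the half-life flagged undefined.
    """
    if isinstance(binned, BinnedCounts):
        if not (0 <= start_index < binned.n_bins):
            raise ParameterError("start_index out of range")
        starts = binned.bin_start_times[start_index:]
        t_min = (starts - starts[0]) / 60.0
        values = binned.counts[start_index:].astype(float)
    else:
        values = np.asarray(binned, dtype=float)
        if times_min is None:
            raise ParameterError("times_min required for plain value series")
        t_min = np.asarray(times_min, dtype=float)
        if t_min.size != values.size:
            raise ParameterError("times and values differ in length")
    if zero_offset is not None:
        values = values + zero_offset
    mask = values > 0
    if int(mask.sum()) < 3:
        raise InsufficientDataError(
            f"need >= 3 strictly positive values, got {int(mask.sum())}")
    t_used = t_min[mask]
    ln_y = np.log(values[mask])
    fit = stats.linregress(t_used, ln_y)
    lam = -float(fit.slope)
    half_life = math.log(2) / lam if lam > 0 else math.nan
    return DecayFit(lambda_=lam, half_life_min=half_life,
                    ln_intercept=float(fit.intercept),
                    r_squared=float(fit.rvalue) ** 2,
                    n_bins_used=int(mask.sum()))


def correlate_effect_concentration(counts_at_times, conc_at_times
                                   ) -> tuple[float, float]:
    """Pearson correlation between binned effect and drug concentration.

    Returns ``(r, p_two_sided)`` with p from the t distribution on n-2
    degrees of freedom.  Zero variance in either series yields
    ``(nan, nan)`` rather than raising.
    """
    x = np.asarray(counts_at_times, dtype=float)
    y = np.asarray(conc_at_times, dtype=float)
    if x.size != y.size:
        raise ParameterError("series differ in length")
    if x.size < 3:
        raise InsufficientDataError("need >= 3 matched time points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan)
    r, p = stats.pearsonr(x, y)
    return (float(r), float(p))
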