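"""Signal conditioning for head-twitch detection.

The detection front end is deliberately simple: a zero-phase Butterworth
band-pass isolates the 70-110 Hz head-twitch band, full-wave rectification
folds the oscillation into a nonnegative trace, and two successive passes
of local-maxima interpolation ("double local maxima") collapse each
multi-cycle wavelet into a single unipolar peak whose prominence and width
the detector can test.  A short-time Fourier spectrogram is provided for
visual inspection of candidate events (the 80-100 Hz signature).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ParameterError
from .recordings import TimeSeries

__all__ = [
    "Envelope",
    "bandpass",
    "rectify",
    "envelope_double_maxima",
    "local_maxima_interpolation",
    "spectrogram",
]


@dataclass(frozen=True)
class Envelope:
    """Nonnegative envelope on the same sample grid as its source trace."""

    series: TimeSeries
    band: tuple[float, float] | None = None
    passes: int = 2

    @property
    def samples(self) -> np.ndarray:
        return self.series.samples

    @property
    def sample_rate(self) -> float:
        return self.series.sample_rate

    @property
    def t0(self) -> float:
        return self.series.t0


def bandpass(ts: TimeSeries, low_hz: float, high_hz: float,
             order: int = 3) -> TimeSeries:
    """Zero-phase Butterworth band-pass.

    The filter is applied forward-backward (``sosfiltfilt``), doubling the
    effective order and cancelling phase delay so that event timestamps are
    not biased by the filter.  Output length equals input length.
    """
    nyquist = ts.sample_rate / 2.0
    if not (0 < low_hz < high_hz < nyquist):
        raise ParameterError(
            f"need 0 < low < high < Nyquist ({nyquist} Hz), "
            f"got ({low_hz}, {high_hz})")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass",
                     fs=ts.sample_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, ts.samples)
    return ts.with_samples(filtered)


def rectify(ts: TimeSeries) -> TimeSeries:
    """Full-wave rectification: pointwise absolute value."""
    return ts.with_samples(np.abs(ts.samples))


def _local_maxima_indices(y: np.ndarray) -> np.ndarray:
    """Strict interior local maxima; plateaus contribute their midpoint.

    Matches :func:`scipy.signal.find_peaks` semantics: a sample strictly
    greater than both neighbors, or the middle sample (rounded down) of a
    flat run strictly greater than the samples flanking it.  Endpoints are
    never maxima here; the interpolation adds them as anchors.
    """
    peaks, _ = sps.find_peaks(y)
    return peaks


def local_maxima_interpolation(y: np.ndarray) -> np.ndarray:
    """One envelope pass: linear interpolation through local maxima.

    The first and last samples are always anchors so the result is defined
    on the full grid without extrapolation.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ParameterError("envelope pass needs at least 3 samples")
    peaks = _local_maxima_indices(y)
    anchors = np.concatenate(([0], peaks, [n - 1]))
    anchors = np.unique(anchors)
    return np.interp(np.arange(n), anchors, y[anchors])


def envelope_double_maxima(ts: TimeSeries,
                           band: tuple[float, float] | None = None) -> Envelope:
    """Two passes of local-maxima interpolation over a rectified trace.

    The first pass rides the half-cycle crests of the rectified
    oscillation; the second smooths the residual scalloping between
    crests, so a burst of k cycles becomes a single unimodal peak provided
    the cycle period is short against the inter-burst gap.
    """
    y = np.asarray(ts.samples, dtype=float)
    if y.size < 3:
        raise ParameterError("envelope needs at least 3 samples")
    if np.any(y < 0):
        raise ParameterError("envelope input must be rectified (nonnegative)")
    env = local_maxima_interpolation(local_maxima_interpolation(y))
    return Envelope(ts.with_samples(env), band=band, passes=2)


def spectrogram(ts: TimeSeries, window_s: float = 0.256,
                overlap: float = 0.9):
    """Short-time Fourier magnitude for visual inspection.

    Returns ``(freqs_hz, times_s, magnitude)`` where magnitude has shape
    (n_freqs, n_times).  Head twitches show a dominant 80-100 Hz component;
    grooming and locomotion stay below 40 Hz.
    """
    nperseg = int(round(window_s * ts.sample_rate))
    if nperseg < 8:
        raise ParameterError("window must span at least 8 samples")
    if nperseg > ts.samples.size:
        raise ParameterError("window longer than signal")
    if not (0 <= overlap < 1):
        raise ParameterError("overlap must be in [0, 1)")
    noverlap = int(nperseg * overlap)
    freqs, times, sxx = sps.spectrogram(
        ts.samples, fs=ts.sample_rate, nperseg=nperseg, noverlap=noverlap,
        mode="magnitude")
    return freqs, times + ts.t0, sxx
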