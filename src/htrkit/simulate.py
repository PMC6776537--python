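"""Seeded generator of synthetic two-channel sessions with ground truth.

The generator emulates the phenomenology of a magnetometer head-twitch
recording:

* Gaussian coil background noise (default SD 0.002 V) and independent
  piezo background noise (default SD 0.0375 V, so that 8 x SD equals the
  0.3 V jump threshold, matching the published threshold-to-noise ratio).
* Head-twitch wavelets: Hann-windowed sums of an 80-100 Hz and a 40-50 Hz
  sinusoid, 50-90 ms long, normalized to a prescribed peak voltage.
* Grooming / locomotor artifacts: band-limited oscillations below 40 Hz
  (locomotor bouts 25-30 Hz) which the 70-110 Hz band-pass rejects.
* Jumps: broadband (30-150 Hz) seeded colored-noise coil wavelets paired
  with a suprathreshold piezo spike within a small jitter of the wavelet
  center.  The coil waveform is stochastic by design so that only a
  fraction of jumps leaks into the detection band, as observed in vivo.
* Event schedules: explicit lists, evenly spaced jittered grids, or a
  Poisson process with exponentially decaying rate r0 * exp(-lambda * t)
  for time-course recovery studies.

Every draw is tied to the spec seed; coil and piezo noise come from
independent substreams, so changing the piezo seed leaves the coil channel
bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ParameterError
from .recordings import (AnnotationSet, DualChannelRecording, EVENT_CLASSES,
                         TimeSeries)

__all__ = [
    "ScheduledEvent",
    "RateModel",
    "SessionSpec",
    "synth_htr_wavelet",
    "synth_groom_artifact",
    "synth_locomotor",
    "synth_jump",
    "poisson_decay_times",
    "uniform_schedule",
    "generate_session",
]

# substream tags: noise streams must stay independent of the schedule
_COIL_STREAM, _PIEZO_STREAM, _SCHED_STREAM = 1, 2, 3


@dataclass(frozen=True)
class ScheduledEvent:
    """One injected event: behavioral class, center time, amplitude, span."""

    cls: str
    time_s: float
    amplitude_v: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.cls not in EVENT_CLASSES:
            raise ParameterError(f"unknown event class {self.cls!r}")
        if self.amplitude_v <= 0 or self.duration_s <= 0:
            raise ParameterError("amplitude and duration must be > 0")


@dataclass(frozen=True)
class RateModel:
    """Poisson schedule with exponentially decaying rate.

    ``r0_per_min`` is the initial event rate, ``decay_per_min`` the rate
    constant lambda; event times are drawn from an inhomogeneous Poisson
    process with intensity r0 * exp(-lambda * t).
    """

    cls: str = "htr"
    r0_per_min: float = 8.0
    decay_per_min: float = np.log(2) / 30.0
    amplitude_v: float = 0.3
    duration_s: float = 0.06

    def __post_init__(self) -> None:
        if self.r0_per_min <= 0 or self.decay_per_min < 0:
            raise ParameterError("rate must be > 0 and decay >= 0")


@dataclass
class SessionSpec:
    """Recipe for one synthetic session.

    Defaults place the detector in its nominal regime: coil noise SD
    0.002 V gives a 15 x SD threshold near 0.03 V, comfortably below the
    0.1-0.5 V head-twitch amplitudes and below the 0.075 V cap (raise the
    noise to exercise the capped regime).
    """

    duration_s: float
    sample_rate: float = 1000.0
    noise_sd_v: float = 0.002
    piezo_noise_sd_v: float = 0.0375
    events: list[ScheduledEvent] = field(default_factory=list)
    rate_model: RateModel | None = None
    seed: int = 0
    piezo_seed: int | None = None
    dual_channel: bool = False
    jump_piezo_amp_v: float = 0.5
    jump_jitter_s: float = 0.05

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be > 0")
        for ev in self.events:
            if not (0 <= ev.time_s < self.duration_s):
                raise ParameterError(
                    f"event at {ev.time_s} s outside [0, {self.duration_s})")


def _hann(n: int) -> np.ndarray:
    return sps.windows.hann(n, sym=True)


def _normalize_peak(x: np.ndarray, amp_v: float) -> np.ndarray:
    peak = np.max(np.abs(x))
    if peak == 0:
        return x
    return x * (amp_v / peak)


def synth_htr_wavelet(sample_rate: float = 1000.0, duration_s: float = 0.06,
                      amp_v: float = 0.3, f_high: float = 90.0,
                      f_low: float = 45.0) -> np.ndarray:
    """Hann-windowed two-component head-twitch wavelet, peak |v| = amp_v.

    The high (80-100 Hz) component dominates so the periodogram peak falls
    in the 80-100 Hz band; the low (40-50 Hz) component reproduces the
    secondary spectral signature of real head twitches.
    """
    if not (80 <= f_high <= 100) or not (40 <= f_low <= 50):
        raise ParameterError("f_high must lie in [80, 100], f_low in [40, 50]")
    if duration_s >= 0.09:
        warnings.warn("wavelet duration >= 90 ms may fail the width criterion",
                      stacklevel=2)
    n = max(3, int(round(duration_s * sample_rate)))
    t = np.arange(n) / sample_rate
    carrier = np.sin(2 * np.pi * f_high * t) + 0.5 * np.sin(2 * np.pi * f_low * t)
    return _normalize_peak(_hann(n) * carrier, amp_v)


def synth_groom_artifact(sample_rate: float = 1000.0, duration_s: float = 1.0,
                         amp_v: float = 0.5, freq_hz: float = 28.0
                         ) -> np.ndarray:
    """Sub-40 Hz grooming bout oscillation, peak |v| = amp_v.

    Band-limited below the detection band, so after the 70-110 Hz
    band-pass its residual RMS is a few percent of the original at most.
    """
    if not (0 < freq_hz < 40):
        raise ParameterError("grooming artifacts must stay below 40 Hz")
    if amp_v == 0:
        return np.zeros(max(3, int(round(duration_s * sample_rate))))
    n = max(3, int(round(duration_s * sample_rate)))
    t = np.arange(n) / sample_rate
    return _normalize_peak(_hann(n) * np.sin(2 * np.pi * freq_hz * t), amp_v)


def synth_locomotor(sample_rate: float = 1000.0, duration_s: float = 1.0,
                    amp_v: float = 0.3, freq_hz: float = 27.0) -> np.ndarray:
    """Locomotor bout: 25-30 Hz oscillation, same construction as grooming."""
    if not (25 <= freq_hz <= 30):
        raise ParameterError("locomotor band is 25-30 Hz")
    return synth_groom_artifact(sample_rate, duration_s, amp_v, freq_hz)


def synth_jump(rng: np.random.Generator, sample_rate: float = 1000.0,
               coil_amp_v: float = 0.2, piezo_amp_v: float = 0.5,
               jitter_s: float = 0.05, duration_s: float = 0.12
               ) -> tuple[np.ndarray, np.ndarray, float]:
    """One jump: broadband coil wavelet + paired piezo spike.

    Returns ``(coil_wavelet, piezo_pulse, piezo_offset_s)`` where the
    offset (drawn uniformly in +/-jitter_s) places the piezo spike
    relative to the coil wavelet center.  The coil wavelet is 30-150 Hz
    colored noise under a Hann window; because its in-band (70-110 Hz)
    energy is random, only a fraction of jumps triggers the detector,
    emulating the in vivo false-positive regime.
    """
    if piezo_amp_v < 0:
        raise ParameterError("piezo_amp_v must be >= 0")
    n = max(16, int(round(duration_s * sample_rate)))
    white = rng.standard_normal(n + 200)  # pad against filter transients
    sos = sps.butter(3, [30.0, 150.0], btype="bandpass", fs=sample_rate,
                     output="sos")
    colored = sps.sosfiltfilt(sos, white)[100:100 + n]
    coil = _normalize_peak(_hann(n) * colored, coil_amp_v)
    # piezo spike: 20 ms half-sine impact transient
    m = max(3, int(round(0.020 * sample_rate)))
    piezo = piezo_amp_v * np.sin(np.pi * np.arange(m) / (m - 1))
    offset = float(rng.uniform(-jitter_s, jitter_s))
    return coil, piezo, offset


def poisson_decay_times(r0_per_min: float, decay_per_min: float,
                        duration_s: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Event times from an inhomogeneous Poisson process by thinning.

    Intensity r0 * exp(-lambda * t) with t in minutes; returns sorted
    times in seconds within ``[0, duration_s)``.
    """
    if r0_per_min <= 0 or decay_per_min < 0 or duration_s <= 0:
        raise ParameterError("invalid rate-model parameters")
    rate_s = r0_per_min / 60.0
    t, out = 0.0, []
    while True:
        t += rng.exponential(1.0 / rate_s)
        if t >= duration_s:
            break
        if rng.uniform() < np.exp(-decay_per_min * t / 60.0):
            out.append(t)
    return np.asarray(out)


def uniform_schedule(n_events: int, duration_s: float, min_gap_s: float,
                     rng: np.random.Generator,
                     edge_s: float = 1.0) -> np.ndarray:
    """Jittered-grid schedule: n times with pairwise gaps >= min_gap_s."""
    if n_events < 1:
        raise ParameterError("n_events must be >= 1")
    usable = duration_s - 2 * edge_s
    slot = usable / n_events
    if slot < min_gap_s:
        raise ParameterError(
            f"cannot fit {n_events} events with {min_gap_s} s gaps "
            f"into {duration_s} s")
    jitter_half = (slot - min_gap_s) / 2
    centers = edge_s + slot * (np.arange(n_events) + 0.5)
    return centers + rng.uniform(-jitter_half, jitter_half, size=n_events)


def _add_at(trace: np.ndarray, wave: np.ndarray, center_idx: int) -> None:
    half = len(wave) // 2
    lo = center_idx - half
    hi = lo + len(wave)
    w_lo = max(0, -lo)
    w_hi = len(wave) - max(0, hi - trace.size)
    lo, hi = max(lo, 0), min(hi, trace.size)
    if lo < hi:
        trace[lo:hi] += wave[w_lo:w_hi]


def generate_session(spec: SessionSpec
                     ) -> tuple[DualChannelRecording, AnnotationSet]:
    """Render a spec into a recording plus ground-truth annotations.

    Deterministic given the spec seed(s).  Scheduled events closer than
    50 ms emit a ground-truth-ambiguity warning but are still rendered.
    """
    fs = spec.sample_rate
    n = int(round(spec.duration_s * fs))
    coil_rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, _COIL_STREAM]))
    piezo_entropy = spec.seed if spec.piezo_seed is None else spec.piezo_seed
    piezo_rng = np.random.default_rng(
        np.random.SeedSequence([piezo_entropy, _PIEZO_STREAM]))
    sched_rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, _SCHED_STREAM]))

    coil = coil_rng.normal(0.0, spec.noise_sd_v, n)
    need_piezo = spec.dual_channel or any(e.cls == "jump" for e in spec.events)
    piezo = (piezo_rng.normal(0.0, spec.piezo_noise_sd_v, n)
             if need_piezo else None)

    events = list(spec.events)
    if spec.rate_model is not None:
        rm = spec.rate_model
        for t in poisson_decay_times(rm.r0_per_min, rm.decay_per_min,
                                     spec.duration_s, sched_rng):
            events.append(ScheduledEvent(rm.cls, float(t), rm.amplitude_v,
                                         rm.duration_s))
    events.sort(key=lambda e: e.time_s)

    gaps = np.diff([e.time_s for e in events])
    if gaps.size and np.any(gaps < 0.050):
        warnings.warn(
            f"{int(np.sum(gaps < 0.050))} event pair(s) closer than 50 ms; "
            "ground truth may be ambiguous", stacklevel=2)

    for ev in events:
        idx = int(round(ev.time_s * fs))
        if ev.cls == "htr":
            _add_at(coil, synth_htr_wavelet(fs, ev.duration_s, ev.amplitude_v),
                    idx)
        elif ev.cls == "groom":
            _add_at(coil, synth_groom_artifact(fs, ev.duration_s,
                                               ev.amplitude_v), idx)
        elif ev.cls == "locomotor":
            _add_at(coil, synth_locomotor(fs, ev.duration_s, ev.amplitude_v),
                    idx)
        elif ev.cls == "jump":
            wave, pulse, offset = synth_jump(
                sched_rng, fs, coil_amp_v=ev.amplitude_v,
                piezo_amp_v=spec.jump_piezo_amp_v,
                jitter_s=spec.jump_jitter_s, duration_s=ev.duration_s)
            _add_at(coil, wave, idx)
            if piezo is not None:
                _add_at(piezo, pulse, idx + int(round(offset * fs)))
        else:  # "other": unstructured broadband blip, coil only
            blip = sched_rng.standard_normal(
                max(3, int(round(ev.duration_s * fs))))
            _add_at(coil, _normalize_peak(_hann(blip.size) * blip,
                                          ev.amplitude_v), idx)

    recording = DualChannelRecording(
        TimeSeries(coil, fs, 0.0, "coil"),
        TimeSeries(piezo, fs, 0.0, "piezo") if piezo is not None else None)
    annotations = AnnotationSet(np.array([e.time_s for e in events]),
                                [e.cls for e in events])
    return recording, annotations
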