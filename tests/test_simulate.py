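"""Synthetic-session generator: waveform contracts, determinism, and
cross-module fidelity."""

import math

import numpy as np
import pytest
from scipy.signal import periodogram

from htrkit import (RateModel, ScheduledEvent, SessionSpec, TimeSeries,
                    annotate_piezo_maxima, bandpass, bin_events, detect_htr,
                    fit_exponential_decay, generate_session, match_events)
from htrkit.errors import ParameterError
from htrkit.recordings import events_from_timestamps
from htrkit.simulate import (synth_groom_artifact, synth_htr_wavelet,
                             synth_jump, synth_locomotor, uniform_schedule)

FS = 1000.0


class TestHtrWavelet:
    def test_peak_normalization(self):
        wave = synth_htr_wavelet(FS, 0.06, 0.5)
        assert np.max(np.abs(wave)) == pytest.approx(0.5, rel=0.01)

    def test_spectral_peak_in_high_band(self):
        wave = synth_htr_wavelet(FS, 0.08, 0.5, f_high=90, f_low=45)
        freqs, power = periodogram(wave, fs=FS, nfft=4096)
        band = (freqs >= 60) & (freqs <= 200)
        assert 80 <= freqs[band][np.argmax(power[band])] <= 100

    def test_detected_as_exactly_one_event(self):
        rec, _ = generate_session(SessionSpec(
            duration_s=20.0, seed=1,
            events=[ScheduledEvent("htr", 10.0, 0.4, 0.06)]))
        events, _ = detect_htr(rec.coil)
        assert len(events) == 1

    def test_frequency_bounds_enforced(self):
        with pytest.raises(ParameterError):
            synth_htr_wavelet(FS, 0.06, 0.5, f_high=120)

    def test_overlong_wavelet_warns(self):
        with pytest.warns(UserWarning, match="width criterion"):
            synth_htr_wavelet(FS, 0.12, 0.5)


class TestLowFrequencyArtifacts:
    def test_groom_burst_triggers_no_detection(self):
        rec, _ = generate_session(SessionSpec(
            duration_s=20.0, seed=2,
            events=[ScheduledEvent("groom", 10.0, 0.5, 1.0)]))
        events, _ = detect_htr(rec.coil)
        assert len(events) == 0

    @pytest.mark.parametrize("synth,freq", [(synth_groom_artifact, 28.0),
                                            (synth_locomotor, 27.0)])
    def test_bandpass_residual_under_5_percent(self, synth, freq):
        wave = synth(FS, 1.0, 0.5, freq)
        padded = np.zeros(int(3 * FS))
        padded[1000:1000 + wave.size] = wave
        residual = bandpass(TimeSeries(padded, FS), 70, 110).samples
        rms_in = np.sqrt(np.mean(wave ** 2))
        rms_out = np.sqrt(np.mean(residual ** 2) * 3)  # same support length
        assert rms_out < 0.05 * rms_in

    def test_zero_amplitude_gives_zero_samples(self):
        assert np.allclose(synth_groom_artifact(FS, 1.0, 0.0), 0.0)

    def test_locomotor_band_enforced(self):
        with pytest.raises(ParameterError):
            synth_locomotor(FS, 1.0, 0.3, freq_hz=40.0)


class TestJump:
    def test_piezo_pulse_found_near_jump_time(self):
        rec, ann = generate_session(SessionSpec(
            duration_s=20.0, seed=3, dual_channel=True,
            events=[ScheduledEvent("jump", 10.0, 0.2, 0.12)]))
        maxima = annotate_piezo_maxima(rec.piezo)
        assert len(maxima) >= 1
        assert np.min(np.abs(maxima.timestamps - 10.0)) <= 0.1

    def test_subthreshold_piezo_amp_not_annotated(self):
        rec, _ = generate_session(SessionSpec(
            duration_s=20.0, seed=4, dual_channel=True,
            jump_piezo_amp_v=0.2,
            events=[ScheduledEvent("jump", 10.0, 0.2, 0.12)]))
        assert len(annotate_piezo_maxima(rec.piezo)) == 0

    def test_leakage_fraction_matches_in_vivo_regime(self):
        """A substantial fraction (> 0.3) of broadband jump wavelets leaks
        into the 70-110 Hz band and triggers detection, as in vivo."""
        triggered = total = 0
        for seed in range(10):
            rng = np.random.default_rng(700 + seed)
            times = uniform_schedule(5, 40.0, 2.0, rng, edge_s=2.0)
            evs = [ScheduledEvent("jump", float(t), 0.2, 0.12)
                   for t in times]
            rec, ann = generate_session(SessionSpec(
                duration_s=40.0, seed=700 + seed, events=evs))
            events, _ = detect_htr(rec.coil)
            from htrkit import event_class_fp_rate
            triggered += event_class_fp_rate(events, ann, 0.1, "jump") * 5
            total += 5
        assert triggered / total > 0.3


class TestGenerateSession:
    def test_same_seed_bit_identical(self):
        spec = dict(duration_s=10.0, seed=5, dual_channel=True,
                    events=[ScheduledEvent("htr", 5.0, 0.3, 0.06)])
        r1, _ = generate_session(SessionSpec(**spec))
        r2, _ = generate_session(SessionSpec(**spec))
        np.testing.assert_array_equal(r1.coil.samples, r2.coil.samples)
        np.testing.assert_array_equal(r1.piezo.samples, r2.piezo.samples)

    def test_annotations_mirror_schedule(self):
        rng = np.random.default_rng(6)
        times = uniform_schedule(20, 60.0, 1.0, rng, edge_s=2.0)
        evs = [ScheduledEvent("htr", float(t), 0.3, 0.06) for t in times]
        _, ann = generate_session(SessionSpec(duration_s=60.0, seed=6,
                                              events=evs))
        assert len(ann.of_class("htr")) == 20

    def test_piezo_substream_independent_of_coil(self):
        base = SessionSpec(duration_s=5.0, seed=7, dual_channel=True)
        alt = SessionSpec(duration_s=5.0, seed=7, piezo_seed=99,
                          dual_channel=True)
        r1, _ = generate_session(base)
        r2, _ = generate_session(alt)
        np.testing.assert_array_equal(r1.coil.samples, r2.coil.samples)
        assert not np.array_equal(r1.piezo.samples, r2.piezo.samples)

    def test_overlapping_events_warn(self):
        with pytest.warns(UserWarning, match="50 ms"):
            generate_session(SessionSpec(
                duration_s=10.0, seed=8,
                events=[ScheduledEvent("htr", 5.00, 0.3, 0.06),
                        ScheduledEvent("htr", 5.02, 0.3, 0.06)]))

    def test_event_outside_duration_rejected(self):
        with pytest.raises(ParameterError):
            SessionSpec(duration_s=10.0,
                        events=[ScheduledEvent("htr", 12.0, 0.3, 0.06)])

    def test_poisson_mode_full_loop_half_life(self):
        """generate -> detect -> bin -> fit recovers the programmed decay.

        One 30-min session at r0 = 16/min, t1/2 = 10 min (6 x 5 min bins)
        keeps the full-signal path affordable while testing the same
        closed loop as the long-form event-train suite."""
        lam = math.log(2) / 10.0
        spec = SessionSpec(duration_s=1800.0, seed=9,
                           rate_model=RateModel(r0_per_min=16.0,
                                                decay_per_min=lam))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            rec, ann = generate_session(spec)
            events, _ = detect_htr(rec.coil)
        b = bin_events(events, 300.0, 0, 1800.0)
        fit = fit_exponential_decay(b)
        assert fit.half_life_min == pytest.approx(10.0, rel=0.3)

    def test_full_loop_sensitivity_and_fdr(self):
        """Standard suite: amplitude >= 20x noise SD -> sensitivity >= 0.99
        with zero false discoveries."""
        rng = np.random.default_rng(10)
        times = uniform_schedule(20, 40.0, 1.0, rng, edge_s=2.0)
        evs = [ScheduledEvent("htr", float(t), 0.3, 0.06) for t in times]
        rec, ann = generate_session(SessionSpec(duration_s=40.0, seed=10,
                                                events=evs))
        events, _ = detect_htr(rec.coil)
        m = match_events(events, ann, 0.1)
        assert m.tp / 20 >= 0.99
        assert m.fp == 0


class TestSchedules:
    def test_uniform_schedule_respects_gaps(self):
        rng = np.random.default_rng(11)
        times = uniform_schedule(50, 120.0, 1.0, rng, edge_s=2.0)
        assert times.size == 50
        assert np.min(np.diff(np.sort(times))) >= 1.0
        assert times.min() >= 2.0 and times.max() <= 118.0

    def test_uniform_schedule_infeasible_rejected(self):
        with pytest.raises(ParameterError):
            uniform_schedule(100, 20.0, 1.0, np.random.default_rng(0))

    def test_poisson_times_sorted_within_window(self):
        from htrkit import poisson_decay_times
        times = poisson_decay_times(8.0, math.log(2) / 30, 3600.0,
                                    np.random.default_rng(12))
        assert np.all(np.diff(times) > 0)
        assert times.min() >= 0 and times.max() < 3600.0
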