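"""Envelope extraction, gait-event detection, cycle normalization and the
six-bin summaries."""

import numpy as np
import pytest
from scipy import signal as sp_signal

from modwalk import emg
from modwalk.errors import (
    InsufficientCyclesError,
    InsufficientDataError,
    MalformedEventsError,
    NoEventsError,
    ZeroChannelError,
)
from modwalk.gaitmetrics import GRFTrace

FS = 2000.0


def _recording(x):
    x = np.atleast_2d(x)
    return emg.EMGRecording(np.tile(x, (8, 1)), FS)


class TestEnvelope:
    def test_zero_input_zero_envelope(self):
        env = emg.envelope(_recording(np.zeros(8000)))
        assert np.allclose(env.samples, 0.0)

    def test_dc_input_removed(self):
        env = emg.envelope(_recording(np.full(8000, 3.7)))
        mid = env.samples[:, 2000:-2000]
        assert np.max(np.abs(mid)) < 1e-6

    def test_sinusoid_plateau_matches_frequency_response(self):
        """An 80 Hz unit sinusoid's envelope plateau equals 2/pi times the
        net (forward-backward) high-pass gain at 80 Hz, computed directly
        from the filter's frequency response."""
        t = np.arange(20000) / FS
        env = emg.envelope(_recording(np.sin(2 * np.pi * 80 * t)))
        sos = sp_signal.butter(2, 40.0, btype="highpass", fs=FS, output="sos")
        _, h = sp_signal.sosfreqz(sos, worN=[80.0], fs=FS)
        expected = (2 / np.pi) * np.abs(h[0]) ** 2
        plateau = env.samples[0, 5000:-5000]
        assert np.max(np.abs(plateau - expected)) / expected < 0.02

    def test_too_short_signal_raises(self):
        with pytest.raises(InsufficientDataError):
            emg.envelope(_recording(np.zeros(100)))

    def test_envelope_nonnegative(self, rng):
        env = emg.envelope(_recording(rng.standard_normal(8000)))
        assert np.all(env.samples >= 0)


def _pulse_fz(starts_s, stops_s, n, fs=FS, amp=700.0):
    fz = np.zeros(n)
    for a, b in zip(starts_s, stops_s):
        fz[int(a * fs) : int(b * fs)] = amp
    return fz


class TestDetectGaitEvents:
    def test_square_pulses_detected_exactly(self):
        n = int(6 * FS)
        starts = [0.5, 1.7, 2.9, 4.1]
        stops = [1.3, 2.5, 3.7, 4.9]
        fz = _pulse_fz(starts, stops, n)
        np_fz = _pulse_fz([1.1, 2.3, 3.5], [1.9, 3.1, 4.3], n)
        trace = GRFTrace(fz, np_fz, np.zeros(n), np.zeros(n), FS)
        events = emg.detect_gait_events(trace)
        assert np.allclose(events.paretic_heel_strikes, starts, atol=1.5 / FS)
        assert np.allclose(events.paretic_toe_offs, stops, atol=1.5 / FS)

    def test_zero_grf_raises(self):
        z = np.zeros(int(2 * FS))
        with pytest.raises(NoEventsError):
            emg.detect_gait_events(GRFTrace(z, z, z, z, FS))

    def test_noise_robust_with_debounce(self, rng):
        """Gaussian noise at half the threshold does not change the events
        found on the clean pulse train."""
        n = int(6 * FS)
        starts = [0.5, 1.7, 2.9, 4.1]
        stops = [1.3, 2.5, 3.7, 4.9]
        fz = _pulse_fz(starts, stops, n)
        np_fz = _pulse_fz([1.1, 2.3, 3.5], [1.9, 3.1, 4.3], n)
        clean = emg.detect_gait_events(GRFTrace(fz, np_fz, fz * 0, fz * 0, FS))
        noisy = emg.detect_gait_events(
            GRFTrace(
                fz + 10.0 * rng.standard_normal(n),
                np_fz + 10.0 * rng.standard_normal(n),
                fz * 0,
                fz * 0,
                FS,
            )
        )
        assert np.allclose(
            clean.paretic_heel_strikes, noisy.paretic_heel_strikes, atol=0.012
        )
        assert len(clean.paretic_toe_offs) == len(noisy.paretic_toe_offs)


def _tiled_recording(template, cycle_s, n_cycles, fs=FS):
    """Envelope recording that is an exact periodic tiling of a 101-point
    template, with heel strikes at the cycle boundaries."""
    n = int(cycle_s * fs * n_cycles) + 1
    t = np.arange(n) / fs
    phase = 100.0 * (t % cycle_s) / cycle_s
    rows = np.stack([np.interp(phase, emg.PCT_GRID, row) for row in template])
    hs = np.arange(n_cycles + 1) * cycle_s
    events = emg.GaitEvents(hs, hs[:-1] + 0.62 * cycle_s,
                            hs[:-1] + 0.5 * cycle_s, hs[:-1] + 0.12 * cycle_s)
    return emg.EMGRecording(rows, fs), events


class TestSegmentAndNormalize:
    def test_periodic_template_identity(self, rng):
        template = rng.random((8, 101))
        template[:, -1] = template[:, 0]  # continuous across the wrap
        rec, events = _tiled_recording(template, 1.0, 4)
        with pytest.warns(UserWarning):  # fewer than 20 cycles
            cyc = emg.segment_and_normalize(rec, events)
        assert np.allclose(cyc.matrix, template, atol=1e-3)
        assert cyc.n_cycles_averaged == 4

    def test_averaging_two_scaled_cycles(self):
        """Cycles carrying template and 2x template average to 1.5x."""
        template = np.abs(np.sin(np.linspace(0, np.pi, 101)))[None, :] * np.ones(
            (8, 1)
        )
        cycle_s, fs = 1.0, FS
        n = int(2 * cycle_s * fs) + 1
        t = np.arange(n) / fs
        phase = 100.0 * (t % cycle_s) / cycle_s
        base = np.interp(phase, emg.PCT_GRID, template[0])
        x = np.where(t < cycle_s, base, 2 * base)
        rec = emg.EMGRecording(np.tile(x, (8, 1)), fs)
        hs = np.array([0.0, 1.0, 2.0])
        events = emg.GaitEvents(hs, hs[:-1] + 0.62, hs[:-1] + 0.5, hs[:-1] + 0.12)
        with pytest.warns(UserWarning):
            cyc = emg.segment_and_normalize(rec, events)
        assert np.allclose(cyc.matrix, 1.5 * template, atol=2e-3)

    def test_jittered_cycles_recover_smooth_template(self, rng):
        """3% duration jitter perturbs a smooth template by < 2% RMS."""
        template = np.tile(
            1.0 + 0.5 * np.sin(2 * np.pi * emg.PCT_GRID / 100.0), (8, 1)
        )
        fs = FS
        durations = 1.0 * rng.lognormal(0, 0.03, size=24)
        hs = np.concatenate([[0.0], np.cumsum(durations)])
        n = int(hs[-1] * fs) + 1
        t = np.arange(n) / fs
        idx = np.clip(np.searchsorted(hs, t, side="right") - 1, 0, len(hs) - 2)
        phase = 100.0 * (t - hs[idx]) / (hs[idx + 1] - hs[idx])
        rows = np.tile(np.interp(phase, emg.PCT_GRID, template[0]), (8, 1))
        events = emg.GaitEvents(hs, hs[:-1] + 0.62 * durations,
                                hs[:-1] + 0.5 * durations, hs[:-1] + 0.12 * durations)
        cyc = emg.segment_and_normalize(emg.EMGRecording(rows, fs), events)
        err = np.linalg.norm(cyc.matrix - template) / np.linalg.norm(template)
        assert err < 0.02

    def test_too_few_heel_strikes(self):
        rec = emg.EMGRecording(np.zeros((8, 4000)), FS)
        events = emg.GaitEvents([0.5], [], [], [])
        with pytest.raises(InsufficientCyclesError):
            emg.segment_and_normalize(rec, events)


def _events_at(np_to=12.0, np_hs=50.0, p_to=62.0, cycle_s=1.0, n_cycles=3):
    hs = np.arange(n_cycles + 1) * cycle_s
    return emg.GaitEvents(
        hs,
        hs[:-1] + p_to / 100 * cycle_s,
        hs[:-1] + np_hs / 100 * cycle_s,
        hs[:-1] + np_to / 100 * cycle_s,
    )


class TestBinAverage:
    def test_constant_envelope(self):
        cyc = emg.CycleEnvelope(np.full((8, 101), 2.5), 5)
        bins = emg.bin_average(cyc, _events_at())
        assert np.allclose(bins.bin_means, 2.5)
        assert np.allclose(bins.bin_edges_pct, [0, 12, 31, 50, 62, 81, 100])

    def test_stance_indicator(self):
        """Envelope equal to 1 during stance (first four bins) and 0 during
        swing gives bin means (1,1,1,1,0,0)."""
        m = np.where(emg.PCT_GRID <= 62.0, 1.0, 0.0)[None, :] * np.ones((8, 1))
        bins = emg.bin_average(emg.CycleEnvelope(m, 5), _events_at())
        # the piecewise-linear 62->63% edge leaks < 0.03 into the first swing bin
        assert np.allclose(bins.bin_means[:, :4], 1.0, atol=0.03)
        assert np.allclose(bins.bin_means[:, 4:], 0.0, atol=0.03)

    def test_linear_ramp_closed_form(self):
        """For a 0-to-1 ramp, each bin mean is the ramp value at the bin
        midpoint (closed-form integral of a linear function)."""
        ramp = (emg.PCT_GRID / 100.0)[None, :] * np.ones((8, 1))
        bins = emg.bin_average(emg.CycleEnvelope(ramp, 5), _events_at())
        edges = bins.bin_edges_pct
        expected = (edges[:-1] + edges[1:]) / 2.0 / 100.0
        assert np.allclose(bins.bin_means, expected[None, :], atol=1e-12)

    def test_bad_event_order_raises(self):
        with pytest.raises(MalformedEventsError):
            emg.bin_average(
                emg.CycleEnvelope(np.ones((8, 101)), 5),
                _events_at(np_to=70.0, np_hs=50.0, p_to=62.0),
            )


class TestNormalizeAmplitude:
    def test_divides_by_max_bin_mean(self):
        rng = np.random.default_rng(0)
        m = rng.random((8, 101)) + 0.1
        cyc = emg.CycleEnvelope(m, 5)
        events = _events_at()
        bins = emg.bin_average(cyc, events)
        norm = emg.normalize_amplitude(cyc, bins)
        maxima = bins.bin_means.max(axis=1)
        assert np.allclose(norm.matrix, m / maxima[:, None])
        # post-condition: recomputed max bin mean is exactly 1 per muscle
        bins2 = emg.bin_average(norm, events)
        assert np.allclose(bins2.bin_means.max(axis=1), 1.0)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        cyc = emg.CycleEnvelope(rng.random((8, 101)) + 0.1, 5)
        events = _events_at()
        once = emg.normalize_amplitude(cyc, emg.bin_average(cyc, events))
        twice = emg.normalize_amplitude(once, emg.bin_average(once, events))
        assert np.allclose(once.matrix, twice.matrix)

    def test_zero_channel_raises_or_drops(self):
        m = np.ones((8, 101))
        m[3] = 0.0
        cyc = emg.CycleEnvelope(m, 5)
        bins = emg.bin_average(cyc, _events_at())
        with pytest.raises(ZeroChannelError):
            emg.normalize_amplitude(cyc, bins)
        with pytest.warns(UserWarning):
            dropped = emg.normalize_amplitude(cyc, bins, on_zero="drop")
        assert dropped.matrix.shape[0] == 7
        assert "VM" not in dropped.muscle_names


class TestGaitEventsInvariants:
    def test_non_increasing_times_rejected(self):
        with pytest.raises(MalformedEventsError):
            emg.GaitEvents([1.0, 0.5], [], [], [])

    def test_double_toe_off_in_one_cycle_rejected(self):
        with pytest.raises(MalformedEventsError):
            emg.GaitEvents([0.0, 1.0, 2.0], [0.3, 0.6], [], [])
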