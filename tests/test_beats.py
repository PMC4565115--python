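"""Beat detection, heart rate and cardiac parameter arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flyheart import (ActivitySegments, BeatEvents, InputError, ParameterError,
                      chamber_params, detect_beats, fractional_shortening,
                      heart_rate, smooth_trace, summarize_recording)

from conftest import make_trace


def cosine_area(n, period_s, fs=128.0, mean=5000.0, amp=2000.0, phase=0.0):
    t = np.arange(n) / fs
    return mean + amp * np.cos(2 * np.pi * t / period_s + phase)


class TestSmoothTrace:
    def test_window_zero_is_identity(self):
        trace = make_trace(np.arange(50.0))
        out = smooth_trace(trace, 0.0)
        np.testing.assert_array_equal(out.area_um2, trace.area_um2)

    def test_constant_trace_unchanged(self):
        trace = make_trace(np.full(64, 7.0))
        out = smooth_trace(trace, 0.1)
        np.testing.assert_allclose(out.area_um2, 7.0)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(0)
        trace = make_trace(rng.normal(0, 1, 512) + 100)
        out = smooth_trace(trace, 0.1)
        assert out.area_um2.var() < trace.area_um2.var()

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ParameterError):
            smooth_trace(make_trace(np.arange(10.0)), 1.0)


class TestDetectBeats:
    def test_pure_cosine_diastoles_at_period_multiples(self):
        trace = make_trace(cosine_area(1280, 0.25))
        events = detect_beats(trace, ActivitySegments.all_on(10.0))
        expected = np.arange(0, 10.0, 0.25)
        detected = trace.times_s[events.diastole_frames]
        # every interior expected maximum matched within one frame
        for t in expected[1:-1]:
            assert np.min(np.abs(detected - t)) <= 1.0 / 128.0 + 1e-9

    def test_constant_trace_no_events(self):
        trace = make_trace(np.full(256, 1000.0))
        events = detect_beats(trace, ActivitySegments.all_on(2.0))
        assert len(events.diastole_frames) == 0

    def test_empty_on_segments_empty_events(self):
        trace = make_trace(cosine_area(256, 0.25))
        events = detect_beats(trace, ActivitySegments.all_off(2.0))
        assert len(events.diastole_frames) == 0
        assert len(events.systole_frames) == 0

    def test_noisy_sinusoid_matches_percycle_argmax_oracle(self):
        rng = np.random.default_rng(42)
        period, fs, dur = 0.5, 128.0, 8.0
        clean = cosine_area(int(dur * fs), period)
        noisy = clean + rng.normal(0, 200.0, len(clean))  # SNR ~10
        trace = make_trace(noisy)
        events = detect_beats(trace, ActivitySegments.all_on(dur))
        # oracle: brute-force argmax of the noisy trace inside each true cycle
        assert len(events.diastole_frames) >= 14
        for d in trace.times_s[events.diastole_frames]:
            cycle = int((d + period / 2) // period)
            lo = max(0, int((cycle - 0.5) * period * fs))
            hi = min(len(noisy), int((cycle + 0.5) * period * fs))
            oracle = lo + np.argmax(noisy[lo:hi])
            assert abs(d - trace.times_s[oracle]) <= 1.0 / fs + 1e-9

    def test_interleaving_invariant(self):
        trace = make_trace(cosine_area(1024, 0.3))
        events = detect_beats(trace, ActivitySegments.all_on(8.0))
        d, s = events.diastole_frames, events.systole_frames
        assert len(s) == len(d) - 1
        for a, b, mid in zip(d[:-1], d[1:], s):
            assert a < mid < b

    def test_min_period_below_nyquist_rejected(self):
        trace = make_trace(cosine_area(256, 0.25))
        with pytest.raises(ParameterError):
            detect_beats(trace, ActivitySegments.all_on(2.0), min_period_s=0.01)


def smoothish(trace):
    return smooth_trace(trace, 5 / 128.0)


class TestHeartRate:
    def test_quarter_second_beats_give_240_bpm(self):
        trace = make_trace(cosine_area(1280, 0.25))
        events = detect_beats(trace, ActivitySegments.all_on(10.0))
        hr = heart_rate(events, trace, ActivitySegments.all_on(10.0))
        assert hr.hr_bpm == pytest.approx(240.0, rel=0.01)
        assert not hr.no_beat

    def test_no_beats_flagged_zero(self):
        trace = make_trace(np.full(256, 1000.0))
        events = detect_beats(trace, ActivitySegments.all_on(2.0))
        hr = heart_rate(events, trace, ActivitySegments.all_on(2.0))
        assert hr.hr_bpm == 0.0
        assert hr.no_beat

    def test_off_period_does_not_affect_hr(self):
        # 4.8 s flat then 7.6 s of 0.5 s beats; intervals must not span the gap
        fs = 128.0
        n_off = int(4.8 * fs)
        on = cosine_area(int(7.6 * fs), 0.5)
        area = np.concatenate([np.full(n_off, on[0]), on])
        trace = make_trace(area)
        segs = ActivitySegments.off_then_on(4.8, 7.6)
        events = detect_beats(trace, segs)
        hr = heart_rate(events, trace, segs)
        assert hr.hr_bpm == pytest.approx(120.0, rel=0.01)


class TestChamberParams:
    def test_single_event_means(self):
        trace = make_trace(np.array([1000.0, 500.0, 1000.0, 400.0, 990.0]))
        events = BeatEvents(diastole_frames=np.array([0]), systole_frames=np.array([]))
        geom = chamber_params(events, trace)
        assert geom.eda_um2 == 1000.0
        assert np.isnan(geom.esa_um2)

    def test_esa_never_exceeds_eda_on_periodic_trace(self):
        trace = make_trace(cosine_area(1024, 0.4))
        events = detect_beats(trace, ActivitySegments.all_on(8.0))
        geom = chamber_params(events, trace)
        assert geom.esa_um2 <= geom.eda_um2

    def test_no_events_all_nan(self):
        trace = make_trace(np.full(16, 5.0))
        geom = chamber_params(BeatEvents(np.array([]), np.array([])), trace)
        assert np.isnan(geom.eda_um2) and np.isnan(geom.esd_x_um)


class TestFractionalShortening:
    @pytest.mark.parametrize("edd, esd, expected", [
        (100.0, 100.0, 0.0),
        (100.0, 50.0, 50.0),
        (80.0, 60.0, 25.0),
    ])
    def test_formula(self, edd, esd, expected):
        assert fractional_shortening(edd, esd) == pytest.approx(expected)

    def test_nonpositive_edd_rejected(self):
        with pytest.raises(InputError):
            fractional_shortening(0.0, 0.0)

    def test_esd_above_edd_warns_negative(self):
        with pytest.warns(UserWarning):
            assert fractional_shortening(50.0, 60.0) == pytest.approx(-20.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(edd=st.floats(1e-3, 1e6), frac=st.floats(0, 1),
           scale=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, edd, frac, scale):
        esd = edd * frac
        fs1 = fractional_shortening(edd, esd)
        fs2 = fractional_shortening(edd * scale, esd * scale)
        assert fs1 == pytest.approx(fs2, rel=1e-9, abs=1e-9)


class TestSummarize:
    def test_beatless_recording_flagged(self):
        trace = make_trace(np.full(256, 4000.0))
        segs = ActivitySegments.all_off(2.0)
        events = BeatEvents(np.array([]), np.array([]))
        params = summarize_recording(trace, events, segs)
        assert params.hr_bpm == 0.0
        assert params.cap_pct == 0.0
        assert "no-beat" in params.flags
        assert params.eda_um2 == pytest.approx(4000.0)  # frozen diastolic geometry
        assert np.isnan(params.esa_um2)

    def test_fs_area_consistent_with_eda_esa(self):
        trace = make_trace(cosine_area(1024, 0.4))
        segs = ActivitySegments.all_on(8.0)
        events = detect_beats(trace, segs)
        params = summarize_recording(trace, events, segs)
        expected = (params.eda_um2 - params.esa_um2) / params.eda_um2 * 100
        assert params.fs_area_pct == pytest.approx(expected)
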