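"""Activity-bout detection, CAP arithmetic, CDD and timelines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flyheart import (ActivitySegments, CardiacParams, InputError,
                      ParameterError, average_cap, build_timeline, cdd_duration,
                      compute_cap, detect_activity)

from conftest import make_trace


def flat_then_sine(off_s, on_s, period_s=0.5, fs=128.0, mean=5000.0,
                   amp=2000.0, noise_sd=0.0, seed=0):
    n_off = int(round(off_s * fs))
    t_on = np.arange(int(round(on_s * fs))) / fs
    on = mean + amp * np.cos(2 * np.pi * t_on / period_s)
    x = np.concatenate([np.full(n_off, mean + amp), on])
    if noise_sd:
        x = x + np.random.default_rng(seed).normal(0, noise_sd, len(x))
    return make_trace(x, fs)


class TestComputeCap:
    def test_worked_example_61_percent(self):
        segs = ActivitySegments.off_then_on(4.8, 7.6)
        cap = compute_cap(segs)
        assert cap == pytest.approx(100 * 7.6 / 12.4)
        assert round(cap) == 61

    def test_all_on_and_all_off(self):
        assert compute_cap(ActivitySegments.all_on(10)) == 100.0
        assert compute_cap(ActivitySegments.all_off(10)) == 0.0

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(durations=st.lists(st.floats(0.2, 10.0), min_size=1, max_size=6),
           scale=st.floats(0.1, 10.0))
    def test_time_reversal_and_rescaling_invariance(self, durations, scale):
        states = ["off" if i % 2 else "on" for i in range(len(durations))]
        fwd = ActivitySegments.from_durations(list(zip(states, durations)))
        rev = ActivitySegments.from_durations(list(zip(states[::-1], durations[::-1])))
        scaled = ActivitySegments.from_durations(
            [(s, d * scale) for s, d in zip(states, durations)])
        assert compute_cap(fwd) == pytest.approx(compute_cap(rev))
        assert compute_cap(fwd) == pytest.approx(compute_cap(scaled))


class TestDetectActivity:
    def test_flat_then_sine_boundary_and_cap(self):
        trace = flat_then_sine(4.8, 7.6, noise_sd=30.0)
        segs = detect_activity(trace)
        states = [s for _, _, s in segs.segments]
        assert states == ["off", "on"]
        off = segs.segments[0]
        assert off[1] == pytest.approx(4.8, abs=0.5)  # within half a window
        assert round(compute_cap(segs)) == 61

    def test_sine_throughout_is_100(self):
        trace = flat_then_sine(0.0, 10.0, noise_sd=30.0)
        assert compute_cap(detect_activity(trace)) == 100.0

    def test_flat_throughout_is_0(self):
        trace = make_trace(np.full(1280, 5000.0))
        assert compute_cap(detect_activity(trace)) == 0.0

    def test_noisy_flat_is_0(self):
        rng = np.random.default_rng(5)
        trace = make_trace(5000.0 + rng.normal(0, 50.0, 1280))
        assert compute_cap(detect_activity(trace)) == 0.0

    def test_noiseless_cap_recovery_within_window_bound(self):
        for off_s, on_s in [(3.0, 5.0), (6.0, 2.0), (2.0, 8.0)]:
            trace = flat_then_sine(off_s, on_s)
            cap = compute_cap(detect_activity(trace))
            truth = 100 * on_s / (off_s + on_s)
            bound = 1.0 / (off_s + on_s) * 100  # (window_s / duration) x 100
            assert abs(cap - truth) <= bound

    def test_trace_shorter_than_window_rejected(self):
        with pytest.raises(ParameterError):
            detect_activity(make_trace(np.arange(32.0)), window_s=1.0)


class TestAverageCap:
    def test_singleton_and_pair(self):
        assert average_cap([61.0]) == 61.0
        assert average_cap([0.0, 100.0]) == 50.0

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            average_cap([])

    def test_five_noisy_recordings_near_schedule_truth(self):
        caps = []
        for seed in range(5):
            trace = flat_then_sine(4.8, 7.6, noise_sd=40.0, seed=seed)
            caps.append(compute_cap(detect_activity(trace)))
        assert abs(average_cap(caps) - 100 * 7.6 / 12.4) < 5.0


class TestCddDuration:
    def test_two_beatless_points_is_16h(self):
        points = [(24, True), (32, False), (40, False), (48, True)]
        res = cdd_duration(points, sampling_interval_h=8.0)
        assert res.duration_h == 16.0
        assert not res.death_censored

    def test_all_beating_is_zero(self):
        assert cdd_duration([(24, True), (32, True)]).duration_h == 0.0

    def test_all_beatless_is_censored_full_span(self):
        res = cdd_duration([(24, False), (32, False), (40, False)])
        assert res.duration_h == 24.0
        assert res.death_censored

    def test_no_points_rejected(self):
        with pytest.raises(InputError):
            cdd_duration([])


def params_row(hr, cap=50.0):
    nan = float("nan")
    beatless = hr == 0
    return CardiacParams(hr_bpm=hr, cap_pct=cap, edd_x_um=100, edd_z_um=80,
                         esd_x_um=nan if beatless else 60,
                         esd_z_um=nan if beatless else 48,
                         eda_um2=6000, esa_um2=nan if beatless else 2200,
                         fs_x_pct=nan if beatless else 40,
                         fs_z_pct=nan if beatless else 40,
                         fs_area_pct=nan if beatless else 63,
                         flags=("no-beat",) if beatless else ())


class TestBuildTimeline:
    def test_pd2_pause_recovered_as_cdd(self):
        groups = [
            ("PD1 24h", [params_row(26.0)] * 5),
            ("PD2 32h", [params_row(0.0, 0.0)] * 5),
            ("PD2 40h", [params_row(0.0, 0.0)] * 5),
            ("PD2 48h", [params_row(17.0, 5.0)] * 5),
        ]
        tl = build_timeline(groups)
        assert tl.cdd_duration_h == 16.0
        assert [p.stage_label for p in tl.points] == [g[0] for g in groups]
        assert tl.points[0].params.hr_bpm == pytest.approx(26.0)

    def test_stage_averaging(self):
        tl = build_timeline([("PD1 24h", [params_row(20.0, 40.0),
                                          params_row(30.0, 60.0)]),
                             ("PD2 32h", [params_row(0.0, 0.0)])])
        assert tl.points[0].params.hr_bpm == pytest.approx(25.0)
        assert tl.points[0].params.cap_pct == pytest.approx(50.0)
        assert tl.points[0].n_recordings == 2

    def test_duplicate_stage_rejected(self):
        with pytest.raises(InputError, match="duplicate"):
            build_timeline([("L2", [params_row(277.0)]),
                            ("L2", [params_row(280.0)])])

    def test_single_stage_cdd_unavailable(self):
        tl = build_timeline([("L2", [params_row(277.0)])])
        assert len(tl.points) == 1
        assert np.isnan(tl.cdd_duration_h)
        assert "cdd-unavailable" in tl.flags

    def test_ordering_is_developmental(self):
        tl = build_timeline([("AD1", [params_row(391.0)]),
                             ("L2", [params_row(277.0)])])
        assert [p.stage_label for p in tl.points] == ["L2", "AD1"]
        assert tl.points[1].params.hr_bpm > tl.points[0].params.hr_bpm
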