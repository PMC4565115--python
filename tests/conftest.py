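"""Shared fixtures: small phantom recordings with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from flyheart import (ActivitySchedule, BeatWaveformSpec, PhantomSpec,
                      RecordingMetadata, generate_recording)


@pytest.fixture(scope="session")
def meta() -> RecordingMetadata:
    return RecordingMetadata()


@pytest.fixture(scope="session")
def small_phantom() -> PhantomSpec:
    """Reduced 96x64 frame keeps per-test segmentation cheap."""
    return PhantomSpec(frame_height_px=96, frame_width_px=64,
                       center_row=48.0, center_col=32.0, rng_seed=7)


@pytest.fixture(scope="session")
def noiseless_phantom(small_phantom) -> PhantomSpec:
    from dataclasses import replace
    return replace(small_phantom, speckle_contrast=0.0, gaussian_noise_sd=0.0)


@pytest.fixture(scope="session")
def small_waveform() -> BeatWaveformSpec:
    """Chamber scaled to fit the 96x64 frame at 2.2 um pixels."""
    return BeatWaveformSpec(beat_period_s=0.5,
                            dia_semiaxis_x_um=30.0, dia_semiaxis_z_um=24.0,
                            sys_semiaxis_x_um=18.0, sys_semiaxis_z_um=14.4)


@pytest.fixture(scope="session")
def noiseless_recording(noiseless_phantom, small_waveform, meta):
    """4 s continuously beating noise-free recording + truth."""
    return generate_recording(noiseless_phantom, small_waveform,
                              ActivitySchedule.all_on(4.0), meta)


@pytest.fixture(scope="session")
def pd1_recording(small_phantom, small_waveform, meta):
    """The worked-example schedule: 4.8 s off then 7.6 s on, with noise."""
    schedule = ActivitySchedule.off_then_on(4.8, 7.6)
    return generate_recording(small_phantom, small_waveform, schedule, meta)


def make_trace(area: np.ndarray, frame_rate_hz: float = 128.0):
    """AreaTrace from a bare area signal (diameters proportional)."""
    from flyheart import AreaTrace

    area = np.asarray(area, dtype=float)
    n = len(area)
    return AreaTrace(times_s=np.arange(n) / frame_rate_hz,
                     area_um2=area,
                     diameter_x_um=np.sqrt(np.abs(area)),
                     diameter_z_um=np.sqrt(np.abs(area)),
                     frame_rate_hz=frame_rate_hz)
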