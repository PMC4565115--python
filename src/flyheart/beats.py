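"""Beat detection and cardiac parameter extraction from chamber-area traces.

The per-frame lumen area trace is the carrier signal: diastole shows up as
a local area maximum, systole as the minimum between consecutive diastoles.
From the detected events the standard M-mode parameters follow — end
diastolic/systolic diameter (EDD/ESD) per axis, end diastolic/systolic
area (EDA/ESA), fractional shortening FS = (EDD - ESD)/EDD x 100, and heart
rate from diastole-to-diastole intervals restricted to periods when the
heart is actually beating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy import signal

from .errors import InputError, ParameterError
from .io import RecordingMetadata
from .segmentation import MaskSeries, mask_geometry

if TYPE_CHECKING:  # pragma: no cover
    from .activity import ActivitySegments

__all__ = [
    "AreaTrace",
    "BeatEvents",
    "CardiacParams",
    "ChamberGeometry",
    "HeartRateResult",
    "extract_area_trace",
    "smooth_trace",
    "estimate_beat_period",
    "detect_beats",
    "heart_rate",
    "chamber_params",
    "fractional_shortening",
    "summarize_recording",
]


@dataclass(frozen=True)
class AreaTrace:
    """Per-frame chamber geometry versus time.

    Failed frames are simply absent: ``times_s`` stays on the acquisition
    clock (multiples of 1/frame_rate_hz) but may have gaps.
    """

    times_s: np.ndarray
    area_um2: np.ndarray
    diameter_x_um: np.ndarray
    diameter_z_um: np.ndarray
    frame_rate_hz: float

    def __post_init__(self) -> None:
        n = len(self.times_s)
        for name in ("area_um2", "diameter_x_um", "diameter_z_um"):
            if len(getattr(self, name)) != n:
                raise InputError(f"{name} length differs from times_s")
        if n >= 2 and not np.all(np.diff(self.times_s) > 0):
            raise InputError("times_s must be strictly increasing")
        for name in ("times_s", "area_um2", "diameter_x_um", "diameter_z_um"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.float64))

    def __len__(self) -> int:
        return len(self.times_s)

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0] + 1.0 / self.frame_rate_hz)


@dataclass(frozen=True)
class BeatEvents:
    """Trace positions of diastolic area maxima and systolic minima.

    Indices refer to positions in the AreaTrace arrays.  Systoles strictly
    interleave with diastoles: at most one systole between consecutive
    diastoles, none outside them.
    """

    diastole_frames: np.ndarray
    systole_frames: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.diastole_frames, dtype=int)
        s = np.asarray(self.systole_frames, dtype=int)
        object.__setattr__(self, "diastole_frames", d)
        object.__setattr__(self, "systole_frames", s)
        if np.any(np.diff(d) <= 0) or np.any(np.diff(s) <= 0):
            raise InputError("event indices must be strictly increasing")
        # each systole must fall strictly between a distinct pair of
        # consecutive diastoles
        gaps = np.searchsorted(d, s)
        if len(s) and (np.any(gaps == 0) or np.any(gaps == len(d))
                       or len(np.unique(gaps)) != len(gaps)):
            raise InputError("systoles must interleave diastoles")

    @property
    def n_beats(self) -> int:
        return max(0, len(self.diastole_frames) - 1)


@dataclass(frozen=True)
class ChamberGeometry:
    eda_um2: float
    esa_um2: float
    edd_x_um: float
    edd_z_um: float
    esd_x_um: float
    esd_z_um: float


@dataclass(frozen=True)
class HeartRateResult:
    hr_bpm: float
    no_beat: bool
    n_intervals: int


@dataclass(frozen=True)
class CardiacParams:
    """One recording's functional and structural summary."""

    hr_bpm: float
    cap_pct: float
    edd_x_um: float
    edd_z_um: float
    esd_x_um: float
    esd_z_um: float
    eda_um2: float
    esa_um2: float
    fs_x_pct: float
    fs_z_pct: float
    fs_area_pct: float
    flags: tuple[str, ...] = ()


def extract_area_trace(masks: MaskSeries, meta: RecordingMetadata) -> AreaTrace:
    """Turn a MaskSeries into an AreaTrace (failed frames dropped)."""
    times, areas, dxs, dzs = [], [], [], []
    for m in masks.good_masks():
        area, dx, dz = mask_geometry(m, meta)
        times.append(m.frame_index / meta.frame_rate_hz)
        areas.append(area)
        dxs.append(dx)
        dzs.append(dz)
    if not times:
        raise InputError("no successfully segmented frames")
    return AreaTrace(times_s=np.array(times), area_um2=np.array(areas),
                     diameter_x_um=np.array(dxs), diameter_z_um=np.array(dzs),
                     frame_rate_hz=meta.frame_rate_hz)


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    pad = w // 2
    xp = np.pad(x, pad, mode="reflect")
    kernel = np.full(w, 1.0 / w)
    return np.convolve(xp, kernel, mode="valid")


def smooth_trace(trace: AreaTrace, window_s: float) -> AreaTrace:
    """Centered moving average; the window is rounded to an odd frame count.

    ``window_s = 0`` is the identity.
    """
    if window_s < 0:
        raise ParameterError("window_s must be >= 0")
    w = int(round(window_s * trace.frame_rate_hz))
    if w <= 1:
        return trace
    if w % 2 == 0:
        w += 1
    if w > len(trace):
        raise ParameterError(f"smoothing window of {w} frames exceeds trace length {len(trace)}")
    return AreaTrace(times_s=trace.times_s,
                     area_um2=_moving_average(trace.area_um2, w),
                     diameter_x_um=_moving_average(trace.diameter_x_um, w),
                     diameter_z_um=_moving_average(trace.diameter_z_um, w),
                     frame_rate_hz=trace.frame_rate_hz)


def estimate_beat_period(trace: AreaTrace, min_period_s: float = 0.1,
                         max_period_s: float = 5.0,
                         min_autocorr: float = 0.3) -> float | None:
    """Dominant beat period from the autocorrelation of the detrended trace.

    Returns None when no credible periodicity is found (flat or noise-only
    traces).  Used to widen the activity-detection window for slow rhythms.
    """
    x = signal.detrend(trace.area_um2)
    if np.ptp(x) == 0 or len(x) < 4:
        return None
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        return None
    ac = np.correlate(x, x, mode="full")[len(x) - 1:] / denom
    fs = trace.frame_rate_hz
    lo = max(2, int(round(min_period_s * fs)))
    hi = min(len(ac) - 1, int(round(max_period_s * fs)), len(x) // 2)
    if hi <= lo:
        return None
    peaks, props = signal.find_peaks(ac[lo:hi], height=min_autocorr)
    if len(peaks) == 0:
        return None
    best = peaks[np.argmax(props["peak_heights"])]
    # prefer the first peak unless a later one is much stronger (harmonics)
    first = peaks[0]
    lag = first if ac[lo + first] >= 0.8 * ac[lo + best] else best
    return float((lo + lag) / fs)


def detect_beats(trace: AreaTrace, on_segments: "ActivitySegments",
                 min_prominence_frac: float = 0.2,
                 min_period_s: float = 0.1) -> BeatEvents:
    """Find diastolic maxima and systolic minima within beating periods.

    Diastoles are local maxima of the area trace with prominence at least
    ``min_prominence_frac`` of the within-segment range and spacing at least
    ``min_period_s``; each systole is the global minimum between consecutive
    diastoles of the same on-segment.  Empty on-segments yield empty events.
    """
    fs = trace.frame_rate_hz
    if not min_period_s > 2.0 / fs:
        raise ParameterError(f"min_period_s must exceed 2/frame_rate = {2.0 / fs:.4f} s")
    distance = max(1, int(round(min_period_s * fs)))
    diastoles: list[int] = []
    systoles: list[int] = []
    for start_s, end_s in on_segments.on_intervals():
        lo = int(np.searchsorted(trace.times_s, start_s - 1e-9))
        hi = int(np.searchsorted(trace.times_s, end_s - 1e-9))
        if hi - lo < 3:
            continue
        seg = trace.area_um2[lo:hi]
        rng = float(np.ptp(seg))
        if rng <= 0:
            continue
        peaks, _ = signal.find_peaks(seg, prominence=min_prominence_frac * rng,
                                     distance=distance)
        for p in peaks:
            diastoles.append(lo + p)
        for a, b in zip(peaks[:-1], peaks[1:]):
            between = seg[a + 1:b]
            if len(between):
                systoles.append(lo + a + 1 + int(np.argmin(between)))
    return BeatEvents(diastole_frames=np.array(sorted(diastoles), dtype=int),
                      systole_frames=np.array(sorted(systoles), dtype=int))


def heart_rate(events: BeatEvents, trace: AreaTrace,
               on_segments: "ActivitySegments") -> HeartRateResult:
    """Heart rate from diastole-to-diastole intervals pooled over on-periods.

    Intervals never span an off-period: only consecutive diastoles falling
    inside the same on-segment contribute.  A recording with fewer than two
    diastoles in every on-segment is flagged ``no_beat`` with HR = 0.
    """
    d_times = trace.times_s[events.diastole_frames] if len(events.diastole_frames) else np.array([])
    intervals: list[float] = []
    for start_s, end_s in on_segments.on_intervals():
        inside = d_times[(d_times >= start_s - 1e-9) & (d_times < end_s + 1e-9)]
        if len(inside) >= 2:
            intervals.extend(np.diff(inside))
    if not intervals:
        return HeartRateResult(hr_bpm=0.0, no_beat=True, n_intervals=0)
    return HeartRateResult(hr_bpm=60.0 / float(np.mean(intervals)),
                           no_beat=False, n_intervals=len(intervals))


def chamber_params(events: BeatEvents, trace: AreaTrace) -> ChamberGeometry:
    """EDA/ESA and per-axis EDD/ESD as means over detected event frames.

    With no events every field is NaN (undefined-parameters convention).
    Values should be read from the *raw* trace: smoothing biases the
    systolic trough upward.
    """
    nan = float("nan")
    d, s = events.diastole_frames, events.systole_frames
    if len(d) == 0:
        return ChamberGeometry(nan, nan, nan, nan, nan, nan)
    eda = float(trace.area_um2[d].mean())
    edd_x = float(trace.diameter_x_um[d].mean())
    edd_z = float(trace.diameter_z_um[d].mean())
    if len(s) == 0:
        return ChamberGeometry(eda, nan, edd_x, edd_z, nan, nan)
    esa = float(trace.area_um2[s].mean())
    esd_x = float(trace.diameter_x_um[s].mean())
    esd_z = float(trace.diameter_z_um[s].mean())
    return ChamberGeometry(eda, esa, edd_x, edd_z, esd_x, esd_z)


def fractional_shortening(edd: float, esd: float) -> float:
    """FS = (EDD - ESD)/EDD x 100, for diameters or areas alike.

    ESD > EDD yields a warning and a negative FS — kept as a data-quality
    signal rather than clipped.
    """
    if not edd > 0:
        raise InputError(f"EDD must be > 0, got {edd}")
    if esd < 0:
        raise InputError(f"ESD must be >= 0, got {esd}")
    if esd > edd:
        warnings.warn("ESD exceeds EDD; negative fractional shortening reported",
                      stacklevel=2)
    return (edd - esd) / edd * 100.0


def _safe_fs(edd: float, esd: float) -> float:
    if not np.isfinite(edd) or not np.isfinite(esd) or not edd > 0:
        return float("nan")
    return fractional_shortening(edd, esd)


def summarize_recording(trace: AreaTrace, events: BeatEvents,
                        activity: "ActivitySegments") -> CardiacParams:
    """Combine events, geometry and activity into one CardiacParams row.

    For a beatless recording the heart sits frozen in diastole, so the
    structural diastolic parameters are taken as whole-trace means, systolic
    parameters are NaN, and the row is flagged ``no-beat``.
    """
    flags: list[str] = []
    hr = heart_rate(events, trace, activity)
    if hr.no_beat:
        flags.append("no-beat")
        geom = ChamberGeometry(
            eda_um2=float(np.mean(trace.area_um2)),
            esa_um2=float("nan"),
            edd_x_um=float(np.mean(trace.diameter_x_um)),
            edd_z_um=float(np.mean(trace.diameter_z_um)),
            esd_x_um=float("nan"), esd_z_um=float("nan"))
    else:
        geom = chamber_params(events, trace)
    return CardiacParams(
        hr_bpm=hr.hr_bpm,
        cap_pct=activity.cap_pct,
        edd_x_um=geom.edd_x_um, edd_z_um=geom.edd_z_um,
        esd_x_um=geom.esd_x_um, esd_z_um=geom.esd_z_um,
        eda_um2=geom.eda_um2, esa_um2=geom.esa_um2,
        fs_x_pct=_safe_fs(geom.edd_x_um, geom.esd_x_um),
        fs_z_pct=_safe_fs(geom.edd_z_um, geom.esd_z_um),
        fs_area_pct=_safe_fs(geom.eda_um2, geom.esa_um2),
        flags=tuple(flags))
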