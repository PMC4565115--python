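"""Cardiac activity bouts, CAP, developmental diastasis and timelines.

The pupal Drosophila heart starts and stops: a recording partitions into
"on" (beating) and "off" (resting) periods.  The cardiac activity period
(CAP) is the percentage of the session the heart spent beating; averaged
over the five recordings taken at each time point it tracks cardiac
function across metamorphosis.  The contiguous beatless span during pupa
day 2, while the chamber is rebuilt, is the cardiac developmental
diastasis (CDD); its duration is scored in multiples of the 8-hour
sampling interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .beats import AreaTrace, CardiacParams
from .errors import InputError, ParameterError
from .stages import SAMPLING_INTERVAL_H, hours_apf, is_pupal, stage_sort_key, validate_stage

__all__ = [
    "ActivitySegments",
    "TimelinePoint",
    "DevelopmentalTimeline",
    "CddResult",
    "detect_activity",
    "compute_cap",
    "average_cap",
    "cdd_duration",
    "build_timeline",
]

_STATES = ("on", "off")


@dataclass(frozen=True)
class ActivitySegments:
    """Contiguous, alternating (start_s, end_s, state) partition of a recording."""

    segments: tuple[tuple[float, float, str], ...]

    def __post_init__(self) -> None:
        segs = tuple((float(a), float(b), s) for a, b, s in self.segments)
        if not segs:
            raise InputError("ActivitySegments needs at least one segment")
        for a, b, s in segs:
            if s not in _STATES:
                raise InputError(f"segment state must be 'on' or 'off', got {s!r}")
            if not b > a:
                raise InputError(f"segment ({a}, {b}) has non-positive duration")
        for (a0, b0, s0), (a1, b1, s1) in zip(segs, segs[1:]):
            if abs(a1 - b0) > 1e-6:
                raise InputError("segments must be contiguous")
            if s0 == s1:
                raise InputError("segment states must alternate")
        object.__setattr__(self, "segments", segs)

    # -- constructors -------------------------------------------------
    @classmethod
    def from_durations(cls, pairs: list[tuple[str, float]],
                       start_s: float = 0.0) -> "ActivitySegments":
        """Build from (state, duration_s) pairs; zero durations are dropped."""
        segs, t = [], start_s
        for state, dur in pairs:
            if dur > 0:
                segs.append((t, t + dur, state))
                t += dur
        return cls(segments=tuple(segs))

    @classmethod
    def all_on(cls, duration_s: float) -> "ActivitySegments":
        return cls(segments=((0.0, float(duration_s), "on"),))

    @classmethod
    def all_off(cls, duration_s: float) -> "ActivitySegments":
        return cls(segments=((0.0, float(duration_s), "off"),))

    @classmethod
    def off_then_on(cls, off_s: float, on_s: float) -> "ActivitySegments":
        return cls.from_durations([("off", off_s), ("on", on_s)])

    # -- queries ------------------------------------------------------
    @property
    def start_s(self) -> float:
        return self.segments[0][0]

    @property
    def end_s(self) -> float:
        return self.segments[-1][1]

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def total_on_s(self) -> float:
        return sum(b - a for a, b, s in self.segments if s == "on")

    @property
    def cap_pct(self) -> float:
        return 100.0 * self.total_on_s / self.duration_s

    def on_intervals(self) -> list[tuple[float, float]]:
        return [(a, b) for a, b, s in self.segments if s == "on"]

    def state_at(self, t: float) -> str:
        for a, b, s in self.segments:
            if a <= t < b:
                return s
        return self.segments[-1][2]


def compute_cap(segments: ActivitySegments) -> float:
    """CAP = 100 x total on-time / total time, at full precision.

    Report rounded to integer percent (``round(compute_cap(...))``).
    """
    if segments.duration_s <= 0:
        raise InputError("zero total duration")
    return segments.cap_pct


def average_cap(recording_caps) -> float:
    """Arithmetic mean CAP over the recordings of one time point."""
    caps = list(recording_caps)
    if not caps:
        raise InputError("no CAP values to average")
    return float(np.mean(caps))


# ---------------------------------------------------------------------
# on/off detection


def _runs(on: np.ndarray) -> list[list[int]]:
    """[[start, end, state01], ...] half-open index runs of a boolean array."""
    edges = np.flatnonzero(np.diff(on.astype(np.int8)))
    bounds = [0, *(edges + 1), len(on)]
    return [[a, b, int(on[a])] for a, b in zip(bounds[:-1], bounds[1:])]


def _merge_short_runs(runs: list[list[int]], min_frames: int) -> list[list[int]]:
    runs = [list(r) for r in runs]
    while len(runs) > 1:
        lengths = [b - a for a, b, _ in runs]
        shortest = int(np.argmin(lengths))
        if lengths[shortest] >= min_frames:
            break
        runs[shortest][2] ^= 1  # flip into the neighbours' state
        merged = [runs[0]]
        for r in runs[1:]:
            if r[2] == merged[-1][2]:
                merged[-1][1] = r[1]
            else:
                merged.append(r)
        runs = merged
    return runs


def _rolling_sd(x: np.ndarray, w: int) -> np.ndarray:
    return (pd.Series(x).rolling(w, center=True, min_periods=max(2, w // 2))
            .std(ddof=0).bfill().ffill().to_numpy())


def _refine_boundaries(runs: list[list[int]], fine_on: np.ndarray,
                       search: int, margin: int) -> list[list[int]]:
    """Snap each coarse on/off boundary to the fine-scale transition."""
    bounds = [r[0] for r in runs[1:]]
    prev = runs[0][0]
    refined = []
    for i, b in enumerate(bounds):
        nxt = runs[i + 1][1]
        to_on = runs[i + 1][2] == 1
        new_b = b
        if to_on:
            # the coarse window reads "on" as soon as it overlaps beating,
            # so the true onset is at/after the coarse boundary: search
            # forward for the first sustained fine activity
            lo, hi = max(prev + 1, b - margin), min(nxt, b + search)
            for j in range(lo, hi):
                if j + 1 < len(fine_on) and fine_on[j] and fine_on[j + 1]:
                    new_b = j
                    break
        else:
            # symmetrically the true offset is at/before the coarse
            # boundary: search backward for the last sustained activity
            lo, hi = max(prev + 1, b - search), min(nxt, b + margin)
            for j in range(hi - 1, lo - 1, -1):
                if j >= 2 and fine_on[j - 1] and fine_on[j - 2]:
                    new_b = j
                    break
        refined.append(int(np.clip(new_b, prev + 1, nxt - 1)))
        prev = refined[-1]
    out = []
    starts = [runs[0][0], *refined]
    ends = [*refined, runs[-1][1]]
    for (a, b), r in zip(zip(starts, ends), runs):
        out.append([a, b, r[2]])
    return out


def detect_activity(trace: AreaTrace, window_s: float = 1.0,
                    k_threshold: float = 4.0, min_segment_s: float = 0.5,
                    *, refine: bool = True, fine_window_frames: int = 5,
                    rel_amplitude_min: float = 0.05) -> ActivitySegments:
    """Partition a trace into beating (on) and resting (off) periods.

    A sliding-window standard deviation of the linearly detrended area
    trace is compared against a noise floor (its 5th percentile): frames
    whose window SD exceeds ``k_threshold`` x floor are "on".  Segments
    shorter than ``min_segment_s`` are merged into their neighbours.

    Two refinements beyond the basic statistic:

    * If no window clears the threshold the trace is homogeneous — all-on
      or all-off — and is classified by its overall relative amplitude
      (detrended SD / median area vs ``rel_amplitude_min``).
    * Each coarse on/off boundary is snapped to the nearest fine-scale
      (``fine_window_frames``) transition, because a window of ``window_s``
      otherwise blurs every bout edge by half a window.
    """
    fs = trace.frame_rate_hz
    n = len(trace)
    w = max(2, int(round(window_s * fs)))
    if w > n:
        raise ParameterError(f"window of {w} frames exceeds trace length {n}")
    x = trace.area_um2
    detrended = signal.detrend(x)
    eps = 1e-8 * max(1.0, float(np.max(np.abs(x))))
    sd = _rolling_sd(detrended, w)
    floor = float(np.percentile(sd, 5))
    threshold = max(k_threshold * floor, eps)

    def segments_from_runs(runs: list[list[int]]) -> ActivitySegments:
        dt = 1.0 / fs
        segs = []
        for a, b, state in runs:
            t0 = trace.times_s[a]
            t1 = trace.times_s[b - 1] + dt if b == n else trace.times_s[b]
            segs.append((t0, t1, "on" if state else "off"))
        return ActivitySegments(segments=tuple(segs))

    on = sd > threshold
    if not on.any():
        # homogeneous trace: all-on vs all-off by relative amplitude
        med = float(np.median(x))
        rel_amp = float(np.std(detrended)) / max(med, eps)
        state = rel_amp > rel_amplitude_min
        return segments_from_runs([[0, n, int(state)]])

    min_frames = max(1, int(round(min_segment_s * fs)))
    runs = _merge_short_runs(_runs(on), min_frames)

    if refine and len(runs) > 1:
        sd_f = _rolling_sd(detrended, max(2, fine_window_frames))
        off_mask = np.zeros(n, dtype=bool)
        for a, b, state in runs:
            if state == 0:
                off_mask[a:b] = True
        if off_mask.any() and (~off_mask).any():
            fine_floor = float(np.percentile(sd_f[off_mask], 5))
            # the fine SD over few frames has a heavy upper tail, so anchor
            # the threshold to the beating amplitude as well as the noise
            typical_on = float(np.median(sd_f[~off_mask]))
            fine_thr = max(k_threshold * fine_floor, 0.2 * typical_on, eps)
            fine_on = sd_f > fine_thr
            runs = _refine_boundaries(runs, fine_on, search=w,
                                      margin=fine_window_frames)
            runs = _merge_short_runs(runs, min_frames)

    return segments_from_runs(runs)


# ---------------------------------------------------------------------
# developmental timelines


@dataclass(frozen=True)
class TimelinePoint:
    """Recording-averaged cardiac parameters at one developmental time point."""

    stage_label: str
    hours_apf: float | None
    params: CardiacParams
    n_recordings: int

    def __post_init__(self) -> None:
        validate_stage(self.stage_label)
        if self.n_recordings < 1:
            raise InputError("n_recordings must be >= 1")

    @property
    def beats_present(self) -> bool:
        return self.params.hr_bpm > 0


@dataclass(frozen=True)
class CddResult:
    duration_h: float
    death_censored: bool


@dataclass(frozen=True)
class DevelopmentalTimeline:
    """Ordered per-stage summaries for one specimen, with the CDD duration."""

    points: tuple[TimelinePoint, ...]
    cdd_duration_h: float
    flags: tuple[str, ...] = ()


def cdd_duration(points, sampling_interval_h: float = SAMPLING_INTERVAL_H) -> CddResult:
    """Cardiac developmental diastasis from (hours_apf, beats_present) points.

    CDD = sampling interval x length of the longest run of consecutive
    pupal time points without beats.  A fully beatless pupal span cannot be
    bounded from the data and is flagged death-censored.
    """
    points = sorted(points, key=lambda p: p[0])
    if not points:
        raise InputError("no pupal time points")
    beat_flags = [bool(b) for _, b in points]
    longest = run = 0
    for b in beat_flags:
        run = run + 1 if not b else 0
        longest = max(longest, run)
    return CddResult(duration_h=sampling_interval_h * longest,
                     death_censored=not any(beat_flags))


def _average_params(rows: list[CardiacParams]) -> CardiacParams:
    def nm(attr: str) -> float:
        vals = np.array([getattr(r, attr) for r in rows], dtype=float)
        if np.all(np.isnan(vals)):
            return float("nan")
        return float(np.nanmean(vals))

    flags = tuple(sorted({f for r in rows for f in r.flags}))
    return CardiacParams(
        hr_bpm=nm("hr_bpm"), cap_pct=average_cap([r.cap_pct for r in rows]),
        edd_x_um=nm("edd_x_um"), edd_z_um=nm("edd_z_um"),
        esd_x_um=nm("esd_x_um"), esd_z_um=nm("esd_z_um"),
        eda_um2=nm("eda_um2"), esa_um2=nm("esa_um2"),
        fs_x_pct=nm("fs_x_pct"), fs_z_pct=nm("fs_z_pct"),
        fs_area_pct=nm("fs_area_pct"), flags=flags)


def build_timeline(per_stage_rows,
                   sampling_interval_h: float = SAMPLING_INTERVAL_H) -> DevelopmentalTimeline:
    """Assemble a DevelopmentalTimeline from per-stage CardiacParams groups.

    ``per_stage_rows`` is a sequence of (stage_label, [CardiacParams, ...])
    — one entry per stage (duplicates are an error), typically five
    recordings per stage.  Points are ordered developmentally; the CDD is
    computed from the pupal points' beat flags.
    """
    groups = list(per_stage_rows)
    if not groups:
        raise InputError("no stages provided")
    labels = [g[0] for g in groups]
    if len(set(labels)) != len(labels):
        raise InputError(f"duplicate stage labels for one specimen: {labels}")
    points = []
    for stage, rows in groups:
        rows = list(rows)
        if not rows:
            raise InputError(f"stage {stage!r} has no recordings")
        points.append(TimelinePoint(stage_label=stage, hours_apf=hours_apf(stage),
                                    params=_average_params(rows),
                                    n_recordings=len(rows)))
    points.sort(key=lambda p: stage_sort_key(p.stage_label))

    flags: list[str] = []
    pupal = [(p.hours_apf, p.beats_present) for p in points if is_pupal(p.stage_label)]
    if len(pupal) < 2:
        flags.append("cdd-unavailable")
        cdd_h = float("nan")
    else:
        cdd = cdd_duration(pupal, sampling_interval_h)
        cdd_h = cdd.duration_h
        if cdd.death_censored:
            flags.append("death-censored")
    return DevelopmentalTimeline(points=tuple(points), cdd_duration_h=cdd_h,
                                 flags=tuple(flags))
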