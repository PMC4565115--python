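"""End-to-end analysis of a single M-mode recording.

Chains segmentation -> area trace -> activity detection -> beat detection
-> parameter summary.  Event detection runs on a lightly smoothed copy of
the trace (5-frame moving average by default); structural parameters are
read from the raw trace at the detected event frames, because smoothing
biases the systolic trough.

The activity-detection window is widened automatically when the trace's
autocorrelation reveals a beat period comparable to the default window:
a sliding-SD window much shorter than one beat would chop slow rhythms
into spurious on/off fragments.
"""

from __future__ import annotations

from dataclasses import dataclass

from .activity import ActivitySegments, detect_activity
from .beats import (AreaTrace, BeatEvents, CardiacParams, detect_beats,
                    estimate_beat_period, extract_area_trace, smooth_trace,
                    summarize_recording)
from .io import MModeRecording
from .segmentation import MaskSeries, segment_series

__all__ = ["AnalysisResult", "analyze_recording"]


@dataclass(frozen=True)
class AnalysisResult:
    params: CardiacParams
    masks: MaskSeries
    trace: AreaTrace          # raw geometry trace
    smoothed: AreaTrace       # trace used for event/activity detection
    events: BeatEvents
    activity: ActivitySegments


def analyze_recording(rec: MModeRecording, *,
                      initial_seed: tuple[int, int] | None = None,
                      tolerance: float | None = None,
                      smooth_window_frames: int = 5,
                      activity_window_s: float = 1.0,
                      k_threshold: float = 4.0,
                      min_segment_s: float = 0.5,
                      min_prominence_frac: float = 0.2,
                      min_period_s: float = 0.1) -> AnalysisResult:
    """Run the full quantification pipeline on one recording."""
    masks = segment_series(rec, initial_seed=initial_seed, tolerance=tolerance)
    trace = extract_area_trace(masks, rec.metadata)
    smoothed = smooth_trace(trace, smooth_window_frames / rec.metadata.frame_rate_hz)

    window_s = activity_window_s
    beat_min_period_s = min_period_s
    period = estimate_beat_period(smoothed, min_period_s=min_period_s)
    if period is not None:
        # the SD window must straddle at least one full beat, and the
        # beat-detection refractory period should scale with the rhythm:
        # slow beats have long flat diastolic plateaus whose pixel-level
        # wiggles otherwise register as twin maxima
        window_s = max(window_s, 1.2 * period)
        beat_min_period_s = max(min_period_s, 0.6 * period)
    window_s = min(window_s, 0.45 * trace.duration_s)

    activity = detect_activity(smoothed, window_s=window_s,
                               k_threshold=k_threshold,
                               min_segment_s=min_segment_s)
    events = detect_beats(smoothed, activity,
                          min_prominence_frac=min_prominence_frac,
                          min_period_s=beat_min_period_s)
    params = summarize_recording(trace, events, activity)
    return AnalysisResult(params=params, masks=masks, trace=trace,
                          smoothed=smoothed, events=events, activity=activity)
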