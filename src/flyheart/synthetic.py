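"""Synthetic M-mode phantom recordings with known ground truth.

The phantom emulates the statistical structure the analysis assumes: a
dark elliptical lumen inside a bright wall, embedded in speckled tissue,
pulsating between diastolic and systolic semi-axes while the heart is
"on" and frozen at full diastole while it is "off".  Speckle is a stylized
model of coherent-imaging noise — a unit-mean exponential intensity field
low-pass filtered to a ~2 px correlation length — not a physical OCM
forward model.

Ground truth (per-frame geometry, beat times, HR, CAP, EDA/ESA) is
returned alongside every recording so the segmentation and beat-analysis
stages can be validated against known answers.

Stage presets pin HR and CAP to the printed developmental-stage means
where those exist (L2 277 bpm; PD1 24h 26 bpm; PD2 48h 17 bpm / CAP 5%;
AD1 391 bpm / CAP 95%; the PD1 16h CAP 61% worked example; L3 CAP 100%);
all other presets, and all chamber dimensions, are the package's own
plausible defaults and are labelled as such.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .activity import ActivitySegments
from .beats import CardiacParams
from .errors import InputError, ParameterError, VocabularyError
from .io import MModeRecording, RecordingMetadata
from .stages import STAGE_ORDER, validate_stage

__all__ = [
    "ActivitySchedule",
    "BeatWaveformSpec",
    "PhantomSpec",
    "SyntheticTruth",
    "StagePreset",
    "StageRecordings",
    "generate_recording",
    "simulate_recording",
    "stage_preset",
    "generate_timeline",
    "sample_stage_params",
    "DEFAULT_TIMELINE_STAGES",
]

#: An activity schedule is structurally the same partition the analysis
#: recovers, so the type is shared.
ActivitySchedule = ActivitySegments


@dataclass(frozen=True)
class BeatWaveformSpec:
    """Beat cycle of the lumen semi-axes (micrometres, seconds).

    Semi-axes follow a raised-cosine cycle from diastolic to systolic
    values and back; ``systole_fraction`` is the fraction of the cycle
    spent contracting (0.5 = symmetric).  Chamber dimensions are synthetic
    defaults, not measured values.
    """

    beat_period_s: float = 0.5
    dia_semiaxis_x_um: float = 55.0
    dia_semiaxis_z_um: float = 45.0
    sys_semiaxis_x_um: float = 33.0
    sys_semiaxis_z_um: float = 27.0
    systole_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.beat_period_s > 0:
            raise ParameterError("beat_period_s must be > 0")
        for s, d in ((self.sys_semiaxis_x_um, self.dia_semiaxis_x_um),
                     (self.sys_semiaxis_z_um, self.dia_semiaxis_z_um)):
            if not (0 < s <= d):
                raise ParameterError("require 0 < systolic semi-axis <= diastolic")
        if not (0 < self.systole_fraction < 1):
            raise ParameterError("systole_fraction must be in (0, 1)")

    def semiaxes_at_phase(self, phase: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Semi-axes at cycle phase in [0, 1); phase 0 is full diastole."""
        phase = np.asarray(phase, dtype=float) % 1.0
        c = self.systole_fraction
        s = np.where(phase < c,
                     0.5 * (1 + np.cos(np.pi * phase / c)),
                     0.5 * (1 - np.cos(np.pi * (phase - c) / (1 - c))))
        ax = self.sys_semiaxis_x_um + (self.dia_semiaxis_x_um - self.sys_semiaxis_x_um) * s
        az = self.sys_semiaxis_z_um + (self.dia_semiaxis_z_um - self.sys_semiaxis_z_um) * s
        return ax, az


@dataclass(frozen=True)
class PhantomSpec:
    """Image-formation parameters of the synthetic phantom."""

    frame_height_px: int = 256
    frame_width_px: int = 128
    center_row: float = 128.0
    center_col: float = 64.0
    wall_thickness_um: float = 12.0
    lumen_mean: float = 40.0
    wall_mean: float = 200.0
    tissue_mean: float = 110.0
    speckle_contrast: float = 0.15
    gaussian_noise_sd: float = 6.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.lumen_mean < self.wall_mean:
            raise ParameterError("lumen must be darker than the wall")
        if self.frame_height_px < 8 or self.frame_width_px < 8:
            raise ParameterError("frame too small")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth twinned with a generated recording."""

    semiaxis_x_um: np.ndarray  # per frame
    semiaxis_z_um: np.ndarray
    area_um2: np.ndarray  # analytic pi*a*b per frame
    beat_times_s: np.ndarray  # diastole instants
    hr_bpm: float
    cap_pct: float
    eda_um2: float
    esa_um2: float


def _check_geometry(phantom: PhantomSpec, waveform: BeatWaveformSpec,
                    meta: RecordingMetadata) -> None:
    max_x = waveform.dia_semiaxis_x_um + phantom.wall_thickness_um
    max_z = waveform.dia_semiaxis_z_um + phantom.wall_thickness_um
    half_w = min(phantom.center_col, phantom.frame_width_px - 1 - phantom.center_col)
    half_h = min(phantom.center_row, phantom.frame_height_px - 1 - phantom.center_row)
    if (max_x / meta.pixel_size_x_um > half_w or max_z / meta.pixel_size_z_um > half_h):
        raise ParameterError(
            "diastolic lumen plus wall does not fit inside the frame")


def generate_recording(phantom: PhantomSpec, waveform: BeatWaveformSpec,
                       schedule: ActivitySchedule, meta: RecordingMetadata,
                       duration_s: float | None = None,
                       ) -> tuple[MModeRecording, SyntheticTruth]:
    """Render a phantom M-mode recording plus its ground truth.

    During on-segments the semi-axes follow the waveform cycle with phase
    reset to full diastole at each on-segment start; during off-segments
    they stay frozen at the diastolic values.  Identical ``rng_seed`` in
    the phantom gives bitwise-identical output.
    """
    fs = meta.frame_rate_hz
    if duration_s is None:
        duration_s = schedule.duration_s
    if abs(schedule.duration_s - duration_s) > 1.0 / fs:
        raise ParameterError(
            f"schedule covers {schedule.duration_s} s but duration_s={duration_s}")
    if not waveform.beat_period_s > 2.0 / fs:
        raise ParameterError(
            f"beat_period_s={waveform.beat_period_s} violates the Nyquist bound 2/fs")
    _check_geometry(phantom, waveform, meta)

    n = int(round(duration_s * fs))
    if n < 2:
        raise ParameterError("duration too short for a recording")
    times = np.arange(n) / fs

    ax = np.full(n, waveform.dia_semiaxis_x_um)
    az = np.full(n, waveform.dia_semiaxis_z_um)
    beat_times: list[float] = []
    for start, end in schedule.on_intervals():
        sel = (times >= start - 1e-9) & (times < end - 1e-9)
        phase = (times[sel] - start) / waveform.beat_period_s
        ax[sel], az[sel] = waveform.semiaxes_at_phase(phase)
        t = start
        while t < end - 1e-9:
            beat_times.append(t)
            t += waveform.beat_period_s

    h, w = phantom.frame_height_px, phantom.frame_width_px
    x_um = (np.arange(w) - phantom.center_col) * meta.pixel_size_x_um
    z_um = (np.arange(h) - phantom.center_row) * meta.pixel_size_z_um
    xg, zg = np.meshgrid(x_um, z_um)
    wall = phantom.wall_thickness_um

    rng = np.random.default_rng(phantom.rng_seed)
    frames = np.empty((n, h, w), dtype=np.float64)
    chunk = 256  # frames per render block; fixed so output is seed-deterministic
    for c0 in range(0, n, chunk):
        c1 = min(c0 + chunk, n)
        a = ax[c0:c1, None, None]
        b = az[c0:c1, None, None]
        r_lumen = (xg / a) ** 2 + (zg / b) ** 2
        r_outer = (xg / (a + wall)) ** 2 + (zg / (b + wall)) ** 2
        img = np.full((c1 - c0, h, w), phantom.tissue_mean)
        img[r_outer <= 1.0] = phantom.wall_mean
        img[r_lumen <= 1.0] = phantom.lumen_mean
        if phantom.speckle_contrast > 0:
            # unit-mean exponential-intensity field, low-passed to ~2 px
            # correlation; sigma 0 on the frame axis keeps frames independent
            u = rng.random(size=(c1 - c0, h, w), dtype=np.float32)
            s = ndimage.gaussian_filter(-np.log1p(-u), sigma=(0, 1, 1))
            s = s / s.mean(axis=(1, 2), keepdims=True)
            sd = s.std(axis=(1, 2), keepdims=True)
            sd[sd == 0] = 1.0
            img = img * (1.0 + phantom.speckle_contrast * (s - 1.0) / sd)
        if phantom.gaussian_noise_sd > 0:
            img = img + phantom.gaussian_noise_sd * rng.standard_normal(
                size=(c1 - c0, h, w), dtype=np.float32)
        frames[c0:c1] = np.clip(img, 0.0, None)

    rec = MModeRecording(frames=frames, metadata=meta)
    any_on = len(schedule.on_intervals()) > 0
    truth = SyntheticTruth(
        semiaxis_x_um=ax, semiaxis_z_um=az,
        area_um2=np.pi * ax * az,
        beat_times_s=np.array(beat_times),
        hr_bpm=60.0 / waveform.beat_period_s if any_on else 0.0,
        cap_pct=schedule.cap_pct,
        eda_um2=np.pi * waveform.dia_semiaxis_x_um * waveform.dia_semiaxis_z_um,
        esa_um2=np.pi * waveform.sys_semiaxis_x_um * waveform.sys_semiaxis_z_um)
    return rec, truth


# ---------------------------------------------------------------------
# stage presets

#: (hr_bpm, cap_pct, chamber scale).  Entries marked "printed" carry the
#: published stage means; everything else is a synthetic interpolated
#: default, as are all chamber scales.
_STAGE_TABLE: dict[str, tuple[float, float, float]] = {
    "L2": (277.0, 88.0, 0.85),       # HR printed
    "L3": (320.0, 100.0, 1.00),      # CAP printed (continuous beating)
    "PD1 16h": (150.0, 61.0, 0.90),  # CAP from the printed worked example
    "PD1 24h": (26.0, 30.0, 0.90),   # HR printed
    "PD2 32h": (0.0, 0.0, 0.75),     # beatless (diastasis)
    "PD2 40h": (0.0, 0.0, 0.75),     # beatless (diastasis)
    "PD2 48h": (17.0, 5.0, 0.75),    # HR and CAP printed
    "PD3 56h": (60.0, 15.0, 0.78),
    "PD3 64h": (120.0, 30.0, 0.80),
    "PD3 72h": (180.0, 50.0, 0.82),
    "PD4 80h": (240.0, 70.0, 0.85),
    "PD4 88h": (300.0, 85.0, 0.87),
    "PD4 96h": (330.0, 90.0, 0.88),
    "PD5 104h": (0.0, 0.0, 0.88),
    "PD5 112h": (0.0, 0.0, 0.88),
    "PD5 120h": (0.0, 0.0, 0.88),
    "AD1": (391.0, 95.0, 0.90),      # HR and CAP printed
}

_BASE_DIA = (55.0, 45.0)  # diastolic semi-axes, synthetic default
_SYS_RATIO = 0.6          # systolic/diastolic semi-axis ratio, synthetic default

#: Longitudinal design: larva, 8-hourly pupa, adult day 1.
DEFAULT_TIMELINE_STAGES: tuple[str, ...] = tuple(
    s for s in STAGE_ORDER if not s.startswith("PD5"))

GENOTYPES = ("control", "dCry-RNAi")

#: Multiplicative deficits applied to the dCry-RNAi genotype.  Synthetic
#: fixture effect sizes chosen to make group comparisons detectable — not
#: measured values.
_RNAI_EFFECTS = {"hr": 0.80, "cap": 0.70, "size": 0.85}


@dataclass(frozen=True)
class StagePreset:
    stage_label: str
    hr_bpm: float
    cap_pct: float
    waveform: BeatWaveformSpec
    schedule: ActivitySchedule


def _make_waveform(hr_bpm: float, size_scale: float) -> BeatWaveformSpec:
    period = 60.0 / hr_bpm if hr_bpm > 0 else 1.0
    dx, dz = _BASE_DIA[0] * size_scale, _BASE_DIA[1] * size_scale
    return BeatWaveformSpec(beat_period_s=period,
                            dia_semiaxis_x_um=dx, dia_semiaxis_z_um=dz,
                            sys_semiaxis_x_um=dx * _SYS_RATIO,
                            sys_semiaxis_z_um=dz * _SYS_RATIO)


def _make_schedule(cap_pct: float, duration_s: float) -> ActivitySchedule:
    if cap_pct >= 100.0:
        return ActivitySchedule.all_on(duration_s)
    if cap_pct <= 0.0:
        return ActivitySchedule.all_off(duration_s)
    on_s = duration_s * cap_pct / 100.0
    return ActivitySchedule.off_then_on(duration_s - on_s, on_s)


def stage_preset(stage_label: str, *, duration_s: float = 30.0) -> StagePreset:
    """Waveform and activity-schedule defaults for a developmental stage.

    HR/CAP equal the published stage means where printed; chamber sizes
    and the remaining stages are synthetic defaults.
    """
    validate_stage(stage_label)
    if stage_label not in _STAGE_TABLE:
        raise VocabularyError(f"no preset for stage {stage_label!r}")
    hr, cap, scale = _STAGE_TABLE[stage_label]
    return StagePreset(stage_label=stage_label, hr_bpm=hr, cap_pct=cap,
                       waveform=_make_waveform(hr, scale),
                       schedule=_make_schedule(cap, duration_s))


def simulate_recording(stage_label: str, genotype: str = "control", *,
                       seed: int = 0, duration_s: float = 30.0,
                       phantom: PhantomSpec | None = None,
                       jitter: bool = False,
                       ) -> tuple[MModeRecording, SyntheticTruth]:
    """Render one phantom recording for a stage/genotype.

    With ``jitter`` False the waveform and schedule are exactly the stage
    preset (with genotype deficits applied); with True, between-recording
    biological variability is added.  ``seed`` drives both the jitter and
    the phantom noise.
    """
    validate_stage(stage_label)
    if genotype not in GENOTYPES:
        raise InputError(f"genotype must be one of {GENOTYPES}")
    rng = np.random.default_rng(seed)
    if jitter:
        waveform, schedule, _, _ = _jittered_stage(rng, stage_label, genotype, duration_s)
    else:
        hr, cap, scale = _STAGE_TABLE[stage_label]
        if genotype == "dCry-RNAi":
            hr *= _RNAI_EFFECTS["hr"]
            cap *= _RNAI_EFFECTS["cap"]
            scale *= _RNAI_EFFECTS["size"]
        waveform = _make_waveform(hr, scale)
        schedule = _make_schedule(cap, duration_s)
    ph = replace(phantom or PhantomSpec(), rng_seed=int(seed) % 2**31)
    meta = RecordingMetadata(stage_label=stage_label, genotype=genotype,
                             specimen_id=f"sim-{seed}")
    return generate_recording(ph, waveform, schedule, meta, duration_s=duration_s)


# ---------------------------------------------------------------------
# timelines


@dataclass(frozen=True)
class StageRecordings:
    stage_label: str
    recordings: tuple[tuple[MModeRecording, SyntheticTruth], ...]


def _jittered_stage(rng: np.random.Generator, stage_label: str,
                    genotype: str, duration_s: float,
                    ) -> tuple[BeatWaveformSpec, ActivitySchedule, float, float]:
    hr, cap, scale = _STAGE_TABLE[stage_label]
    if genotype == "dCry-RNAi":
        hr *= _RNAI_EFFECTS["hr"]
        cap *= _RNAI_EFFECTS["cap"]
        scale *= _RNAI_EFFECTS["size"]
    # between-recording biological variability
    if hr > 0:
        hr *= 1.0 + 0.03 * rng.standard_normal()
    if 0 < cap < 100:
        cap = float(np.clip(cap + 3.0 * rng.standard_normal(), 1.0, 99.0))
    scale *= 1.0 + 0.02 * rng.standard_normal()
    waveform = _make_waveform(hr, scale)
    return waveform, _make_schedule(cap, duration_s), hr, cap


def sample_stage_params(rng: np.random.Generator, stage_label: str,
                        genotype: str = "control") -> CardiacParams:
    """Draw one recording's *true* CardiacParams for a stage and genotype.

    Truth-level sampling (no image rendering) — used to build parameter
    tables for statistical power studies without paying the image-synthesis
    cost.
    """
    validate_stage(stage_label)
    if genotype not in GENOTYPES:
        raise InputError(f"genotype must be one of {GENOTYPES}")
    waveform, _, hr, cap = _jittered_stage(rng, stage_label, genotype, 30.0)
    eda = np.pi * waveform.dia_semiaxis_x_um * waveform.dia_semiaxis_z_um
    esa = np.pi * waveform.sys_semiaxis_x_um * waveform.sys_semiaxis_z_um
    edd_x, edd_z = 2 * waveform.dia_semiaxis_x_um, 2 * waveform.dia_semiaxis_z_um
    esd_x, esd_z = 2 * waveform.sys_semiaxis_x_um, 2 * waveform.sys_semiaxis_z_um
    no_beat = hr <= 0
    nan = float("nan")
    return CardiacParams(
        hr_bpm=max(hr, 0.0), cap_pct=cap,
        edd_x_um=edd_x, edd_z_um=edd_z,
        esd_x_um=nan if no_beat else esd_x, esd_z_um=nan if no_beat else esd_z,
        eda_um2=eda, esa_um2=nan if no_beat else esa,
        fs_x_pct=nan if no_beat else (edd_x - esd_x) / edd_x * 100,
        fs_z_pct=nan if no_beat else (edd_z - esd_z) / edd_z * 100,
        fs_area_pct=nan if no_beat else (eda - esa) / eda * 100,
        flags=("no-beat",) if no_beat else ())


def generate_timeline(specimen_seed: int, genotype: str = "control", *,
                      stages: tuple[str, ...] = DEFAULT_TIMELINE_STAGES,
                      duration_s: float = 30.0, n_recordings: int = 5,
                      phantom: PhantomSpec | None = None,
                      meta_kwargs: dict | None = None,
                      ) -> list[StageRecordings]:
    """Simulate one specimen's longitudinal study: ``n_recordings`` phantom
    recordings at every stage (default five, matching the acquisition
    design), deterministic in ``specimen_seed``.

    The dCry-RNAi genotype applies fixed multiplicative deficits (slower
    HR, lower CAP, smaller chamber) so genotype comparisons carry a real
    effect.
    """
    if genotype not in GENOTYPES:
        raise InputError(f"genotype must be one of {GENOTYPES}")
    base = phantom or PhantomSpec()
    meta_kwargs = meta_kwargs or {}
    ss = np.random.SeedSequence(specimen_seed)
    out = []
    for stage, stage_ss in zip(stages, ss.spawn(len(stages))):
        recs = []
        for rec_idx, rec_ss in enumerate(stage_ss.spawn(n_recordings)):
            rng = np.random.default_rng(rec_ss)
            waveform, schedule, _, _ = _jittered_stage(rng, stage, genotype, duration_s)
            ph = replace(base, rng_seed=int(rec_ss.generate_state(1)[0] % 2**31))
            meta = RecordingMetadata(stage_label=stage,
                                     specimen_id=f"sim-{specimen_seed}",
                                     genotype=genotype, **meta_kwargs)
            recs.append(generate_recording(ph, waveform, schedule, meta,
                                           duration_s=duration_s))
        out.append(StageRecordings(stage_label=stage, recordings=tuple(recs)))
    return out
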