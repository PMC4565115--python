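"""Recording, mask and parameter-table I/O.

An M-mode recording is stored on disk as a multi-page TIFF (one page per
frame, 16-bit unsigned) plus a JSON metadata sidecar carrying the frame
rate, pixel pitches and specimen annotations.  In memory frames are float64
and the frame axis comes first: ``frames[k]`` is the cross-section acquired
at time ``k / frame_rate_hz`` seconds (timestamps at frame start, 0-based).

Parameter tables are pandas DataFrames with a fixed, documented column set
and are written as plain CSV.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import InputError, MetadataError
from .stages import validate_stage

logger = logging.getLogger(__name__)

SIDECAR_KEYS = (
    "frame_rate_hz",
    "pixel_size_x_um",
    "pixel_size_z_um",
    "stage_label",
    "specimen_id",
    "genotype",
)

#: Fixed ParamTable column order.  Units are carried in the column names:
#: _um (micrometres), _um2 (square micrometres), _bpm (beats/minute),
#: _pct (percent).
PARAM_COLUMNS = (
    "specimen_id",
    "stage_label",
    "recording_index",
    "hr_bpm",
    "cap_pct",
    "edd_x_um",
    "edd_z_um",
    "esd_x_um",
    "esd_z_um",
    "eda_um2",
    "esa_um2",
    "fs_x_pct",
    "fs_z_pct",
    "fs_area_pct",
    "flags",
)


@dataclass(frozen=True)
class RecordingMetadata:
    """Acquisition metadata for one M-mode recording.

    Parameters
    ----------
    frame_rate_hz:
        Frames per second; the acquisition default is 128 Hz.
    pixel_size_x_um, pixel_size_z_um:
        Transverse and axial (depth) pixel pitch in micrometres.
    stage_label:
        Developmental stage from the controlled vocabulary, or "unknown".
    specimen_id, genotype:
        Free-text annotations.
    """

    frame_rate_hz: float = 128.0
    pixel_size_x_um: float = 2.2
    pixel_size_z_um: float = 2.2
    stage_label: str = "unknown"
    specimen_id: str = ""
    genotype: str = ""

    def __post_init__(self) -> None:
        if not self.frame_rate_hz > 0:
            raise MetadataError(f"frame_rate_hz must be > 0, got {self.frame_rate_hz}")
        if not (self.pixel_size_x_um > 0 and self.pixel_size_z_um > 0):
            raise MetadataError("pixel sizes must be > 0")
        validate_stage(self.stage_label)

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_x_um * self.pixel_size_z_um

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class MModeRecording:
    """A time-ordered stack of 2D cross-sectional intensity frames.

    ``frames`` has axes (time, depth-rows, transverse-columns) and
    non-negative float values.
    """

    frames: np.ndarray
    metadata: RecordingMetadata

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float64)
        if frames.ndim != 3:
            raise InputError(f"frames must be 3-D (time, rows, cols), got ndim={frames.ndim}")
        if frames.shape[0] < 2:
            raise InputError(f"recording needs at least 2 frames, got {frames.shape[0]}")
        if np.any(frames < 0):
            raise InputError("frame intensities must be non-negative")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.metadata.frame_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        """Timestamp of each frame (frame start), seconds."""
        return np.arange(self.n_frames) / self.metadata.frame_rate_hz


def read_recording(stack_path: str | Path, sidecar_path: str | Path) -> MModeRecording:
    """Read a multi-page TIFF stack and its JSON metadata sidecar.

    Raises
    ------
    InputError
        Missing/corrupt stack, fewer than 2 frames, or inconsistent page shapes.
    MetadataError
        Sidecar missing or lacking ``frame_rate_hz`` (never silently defaulted).
    """
    stack_path, sidecar_path = Path(stack_path), Path(sidecar_path)
    if not stack_path.exists():
        raise InputError(f"stack file not found: {stack_path}")
    if not sidecar_path.exists():
        raise MetadataError(f"metadata sidecar not found: {sidecar_path}")
    try:
        with tifffile.TiffFile(stack_path) as tif:
            shapes = {page.shape for page in tif.pages}
            if len(shapes) > 1:
                raise InputError(f"stack pages have inconsistent shapes: {shapes}")
            frames = tif.asarray()
    except InputError:
        raise
    except Exception as exc:  # corrupt / unreadable container
        raise InputError(f"could not read image stack {stack_path}: {exc}") from exc
    if frames.ndim == 2:
        raise InputError("recording needs at least 2 frames, got a single page")

    try:
        sidecar = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise MetadataError(f"sidecar is not valid JSON: {exc}") from exc
    if "frame_rate_hz" not in sidecar:
        raise MetadataError(f"sidecar {sidecar_path} lacks required key 'frame_rate_hz'")
    defaults = RecordingMetadata()
    kwargs = {}
    for key in SIDECAR_KEYS:
        if key in sidecar:
            kwargs[key] = sidecar[key]
        else:
            kwargs[key] = getattr(defaults, key)
            logger.info("sidecar %s missing optional key %r; defaulting to %r",
                        sidecar_path, key, kwargs[key])
    return MModeRecording(frames=np.asarray(frames, dtype=np.float64),
                          metadata=RecordingMetadata(**kwargs))


def write_recording(rec: MModeRecording, stack_path: str | Path,
                    sidecar_path: str | Path, *, force: bool = False) -> None:
    """Write a recording as 16-bit multi-page TIFF + JSON sidecar.

    Integer-valued intensities in [0, 65535] round-trip bit-exactly.
    Refuses to overwrite existing files unless ``force`` is set.
    """
    stack_path, sidecar_path = Path(stack_path), Path(sidecar_path)
    for p in (stack_path, sidecar_path):
        if p.exists() and not force:
            raise InputError(f"refusing to overwrite existing file {p} (pass force=True)")
    if np.any(rec.frames > np.iinfo(np.uint16).max):
        raise InputError("intensities exceed the 16-bit file range")
    data = np.round(rec.frames).astype(np.uint16)
    tifffile.imwrite(stack_path, data, photometric="minisblack")
    sidecar_path.write_text(json.dumps(rec.metadata.to_dict(), indent=2) + "\n")


@dataclass
class ParamTable:
    """Per-recording cardiac parameter rows keyed by (specimen, stage, recording).

    Thin wrapper over a pandas DataFrame with the fixed :data:`PARAM_COLUMNS`
    column set.
    """

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=PARAM_COLUMNS))

    def __post_init__(self) -> None:
        missing = set(PARAM_COLUMNS) - set(self.frame.columns)
        if missing:
            raise InputError(f"ParamTable missing columns: {sorted(missing)}")
        self.frame = self.frame.loc[:, list(PARAM_COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def add_row(self, specimen_id: str, stage_label: str, recording_index: int,
                params) -> None:
        """Append one CardiacParams result row."""
        row = {
            "specimen_id": specimen_id,
            "stage_label": stage_label,
            "recording_index": recording_index,
            "hr_bpm": params.hr_bpm,
            "cap_pct": params.cap_pct,
            "edd_x_um": params.edd_x_um,
            "edd_z_um": params.edd_z_um,
            "esd_x_um": params.esd_x_um,
            "esd_z_um": params.esd_z_um,
            "eda_um2": params.eda_um2,
            "esa_um2": params.esa_um2,
            "fs_x_pct": params.fs_x_pct,
            "fs_z_pct": params.fs_z_pct,
            "fs_area_pct": params.fs_area_pct,
            "flags": ";".join(params.flags),
        }
        new = pd.DataFrame([row]).loc[:, list(PARAM_COLUMNS)]
        if len(self.frame) == 0:
            self.frame = new
        else:
            self.frame = pd.concat([self.frame, new], ignore_index=True)


def write_param_table(table: ParamTable, path: str | Path) -> None:
    """Write a ParamTable as CSV (4-decimal floats, NaN as empty fields)."""
    if len(table) == 0:
        raise InputError("refusing to write an empty parameter table")
    table.frame.to_csv(path, index=False, float_format="%.4f", na_rep="")


def read_param_table(path: str | Path) -> ParamTable:
    path = Path(path)
    if not path.exists():
        raise InputError(f"parameter table not found: {path}")
    frame = pd.read_csv(path)
    if "flags" in frame.columns:
        frame["flags"] = frame["flags"].fillna("")
    return ParamTable(frame=frame)
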