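"""Reading and writing radiometric temperature rasters and recording manifests.

All temperatures are degrees Celsius throughout the package. Two on-disk frame
formats are supported:

``csv``
    The raw temperature matrix, one image row per line, comma-separated
    floats printed to 4 decimal places (0.1 mK), no header.

``tiff16``
    Single-channel unsigned 16-bit little-endian TIFF holding counts, with
    ``temp = count * scale + offset``. The scale/offset pair lives in a YAML
    sidecar (or in the recording manifest), not in TIFF tags, so any TIFF
    reader can consume the pixel data. The default quantisation step of
    0.01 K is strictly finer than the camera's NETD (40 mK), so quantisation
    never dominates sensor noise.

A recording is a directory of frame files plus a versioned YAML manifest
(``schema: limbtherm-recording/1``) listing the frame files in order together
with the frame rate, imaging position and subject/environment metadata.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml

__all__ = [
    "TEMP_MIN_C",
    "TEMP_MAX_C",
    "ImagingPosition",
    "Side",
    "Region",
    "Diagnosis",
    "ThermalFrame",
    "ThermalRecording",
    "SubjectRecord",
    "write_frame",
    "read_frame",
    "write_recording",
    "load_recording",
]

#: Operating range of the radiometric camera, degC. Values outside are rejected.
TEMP_MIN_C = -40.0
TEMP_MAX_C = 650.0

FRAME_SCHEMA = "limbtherm-frame/1"
RECORDING_SCHEMA = "limbtherm-recording/1"

DEFAULT_TIFF_SCALE = 0.01  # K per count
DEFAULT_TIFF_OFFSET = 0.0  # degC at count 0


class ImagingPosition(str, enum.Enum):
    """Camera/subject arrangement of one video recording."""

    anterior_sitting = "anterior_sitting"
    anterior_standing = "anterior_standing"
    left_lateral_standing = "left_lateral_standing"
    right_lateral_standing = "right_lateral_standing"


class Side(str, enum.Enum):
    left = "left"
    right = "right"
    both = "both"


class Region(str, enum.Enum):
    """Presenting-complaint region: where the subject reports pain."""

    hip_thigh = "hip_thigh"
    knee = "knee"
    lower_leg = "lower_leg"
    ankle = "ankle"


class Diagnosis(str, enum.Enum):
    soft_tissue_injury = "soft_tissue_injury"
    irritable_hip = "irritable_hip"
    fracture = "fracture"
    other = "other"
    unknown = "unknown"


@dataclass
class ThermalFrame:
    """One 2-D temperature raster (degC); the unit of all pixel statistics.

    Row 0 is the image top, column 0 the image left (conventional raster
    order). Temperatures must be finite and within the camera's operating
    range.
    """

    temps: np.ndarray
    timestamp: float = 0.0
    index: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.temps, dtype=float)
        if t.ndim != 2 or t.size == 0:
            raise ValueError("temperature raster must be a non-empty 2-D matrix")
        if not np.all(np.isfinite(t)):
            raise ValueError("temperature raster contains non-finite values")
        lo, hi = float(t.min()), float(t.max())
        if lo < TEMP_MIN_C or hi > TEMP_MAX_C:
            raise ValueError(
                f"temperatures [{lo:.2f}, {hi:.2f}] degC outside camera range "
                f"[{TEMP_MIN_C}, {TEMP_MAX_C}] degC"
            )
        if self.index < 0:
            raise ValueError("frame index must be >= 0")
        self.temps = t

    @property
    def shape(self) -> tuple[int, int]:
        return self.temps.shape  # type: ignore[return-value]


@dataclass
class ThermalRecording:
    """An ordered sequence of frames from one acquisition.

    Frame indices must run 0..n-1 and timestamps must be non-decreasing; all
    frames share one shape.
    """

    frames: list[ThermalFrame]
    rate_hz: float
    position: ImagingPosition
    room_temp_c: float = 23.0
    humidity_pct: float = 50.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("recording contains no frames")
        if self.rate_hz <= 0:
            raise ValueError("frame rate must be positive")
        self.position = ImagingPosition(self.position)
        shape = self.frames[0].shape
        prev_ts = -np.inf
        for i, fr in enumerate(self.frames):
            if fr.index != i:
                raise ValueError(
                    f"frame indices must be consecutive from 0; got {fr.index} at {i}"
                )
            if fr.shape != shape:
                raise ValueError(
                    f"frame {i} shape {fr.shape} differs from {shape}"
                )
            if fr.timestamp < prev_ts:
                raise ValueError("timestamps must be non-decreasing")
            prev_ts = fr.timestamp

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    def temps_stack(self) -> np.ndarray:
        """All frames as one (n_frames, rows, cols) array."""
        return np.stack([f.temps for f in self.frames])


@dataclass
class SubjectRecord:
    """Clinical metadata for one subject."""

    subject_id: str
    age_years: float
    sex: str
    height_cm: float
    weight_kg: float
    body_temp_c: float
    affected_side: Side
    complaint_region: Region
    onset_hours: float
    diagnosis: Diagnosis
    trauma: bool = False
    weight_bearing: bool = True

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValueError("age must be >= 0")
        if self.onset_hours < 0:
            raise ValueError("onset_hours must be >= 0")
        self.affected_side = Side(self.affected_side)
        self.complaint_region = Region(self.complaint_region)
        self.diagnosis = Diagnosis(self.diagnosis)


# ---------------------------------------------------------------------------
# Frame I/O
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".yaml")


def write_frame(
    frame: ThermalFrame,
    path: str | Path,
    format: str = "csv",
    *,
    scale: float = DEFAULT_TIFF_SCALE,
    offset: float = DEFAULT_TIFF_OFFSET,
    sidecar: bool = True,
) -> None:
    """Write one frame to disk as ``csv`` or ``tiff16``.

    For ``tiff16`` the stored counts are ``round((temp - offset) / scale)``
    and must fit in 16 bits; ``scale``/``offset`` are written to a YAML
    sidecar next to the file unless ``sidecar=False`` (used when a recording
    manifest carries them instead).
    """
    path = Path(path)
    if format == "csv":
        np.savetxt(path, frame.temps, fmt="%.4f", delimiter=",")
    elif format == "tiff16":
        counts = np.rint((frame.temps - offset) / scale)
        if counts.min() < 0 or counts.max() > np.iinfo(np.uint16).max:
            raise ValueError(
                "temperatures out of 16-bit count range for "
                f"scale={scale}, offset={offset}"
            )
        tifffile.imwrite(path, counts.astype("<u2"))
        if sidecar:
            meta = {
                "schema": FRAME_SCHEMA,
                "scale": float(scale),
                "offset": float(offset),
                "timestamp": float(frame.timestamp),
                "index": int(frame.index),
            }
            _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))
    else:
        raise ValueError(f"unknown frame format: {format!r}")


def read_frame(
    path: str | Path,
    format: str = "csv",
    *,
    scale: float | None = None,
    offset: float | None = None,
    timestamp: float | None = None,
    index: int | None = None,
) -> ThermalFrame:
    """Read one frame written by :func:`write_frame`.

    For ``tiff16``, ``scale``/``offset`` default to the YAML sidecar; a
    missing sidecar with no explicit scale is an error. ``timestamp`` and
    ``index`` override any sidecar values (the recording loader supplies
    them from the manifest).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"frame file not found: {path}")
    if format == "csv":
        temps = np.loadtxt(path, delimiter=",", ndmin=2)
        ts, idx = timestamp or 0.0, index or 0
    elif format == "tiff16":
        meta: dict = {}
        if scale is None or offset is None:
            sc_path = _sidecar_path(path)
            if not sc_path.exists():
                raise FileNotFoundError(
                    f"tiff16 frame {path} has no scale/offset sidecar {sc_path}"
                )
            meta = yaml.safe_load(sc_path.read_text())
        scale = float(meta["scale"]) if scale is None else float(scale)
        offset = float(meta["offset"]) if offset is None else float(offset)
        counts = tifffile.imread(path).astype(float)
        temps = counts * scale + offset
        ts = timestamp if timestamp is not None else float(meta.get("timestamp", 0.0))
        idx = index if index is not None else int(meta.get("index", 0))
    else:
        raise ValueError(f"unknown frame format: {format!r}")
    return ThermalFrame(temps=temps, timestamp=ts, index=idx)


# ---------------------------------------------------------------------------
# Recording I/O
# ---------------------------------------------------------------------------


def write_recording(
    recording: ThermalRecording,
    directory: str | Path,
    *,
    frame_format: str = "csv",
    scale: float = DEFAULT_TIFF_SCALE,
    offset: float = DEFAULT_TIFF_OFFSET,
) -> Path:
    """Write all frames plus a ``manifest.yaml``; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ext = "csv" if frame_format == "csv" else "tiff"
    names = []
    for fr in recording.frames:
        name = f"frame_{fr.index:04d}.{ext}"
        write_frame(
            fr, directory / name, frame_format,
            scale=scale, offset=offset, sidecar=False,
        )
        names.append(name)
    manifest = {
        "schema": RECORDING_SCHEMA,
        "subject_id": recording.subject_id,
        "position": recording.position.value,
        "rate_hz": float(recording.rate_hz),
        "room_temp_c": float(recording.room_temp_c),
        "humidity_pct": float(recording.humidity_pct),
        "frame_format": frame_format,
        "tiff_scale": float(scale),
        "tiff_offset": float(offset),
        "frames": names,
        "timestamps": [float(f.timestamp) for f in recording.frames],
    }
    manifest_path = directory / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path


def load_recording(manifest_path: str | Path) -> ThermalRecording:
    """Load a recording from its manifest; validates order, shape, position."""
    manifest_path = Path(manifest_path)
    doc = yaml.safe_load(manifest_path.read_text())
    if doc.get("schema") != RECORDING_SCHEMA:
        raise ValueError(
            f"unsupported manifest schema {doc.get('schema')!r} in {manifest_path}"
        )
    names: Sequence[str] = doc.get("frames") or []
    if not names:
        raise ValueError(f"manifest {manifest_path} lists no frames")
    try:
        position = ImagingPosition(doc["position"])
    except ValueError as err:
        raise ValueError(
            f"unknown imaging position {doc['position']!r} in {manifest_path}"
        ) from err
    fmt = doc.get("frame_format", "csv")
    rate = float(doc["rate_hz"])
    timestamps = doc.get("timestamps") or [i / rate for i in range(len(names))]
    base = manifest_path.parent
    frames = []
    for i, name in enumerate(names):
        fpath = base / name
        if not fpath.exists():
            raise FileNotFoundError(
                f"frame file {name!r} listed in {manifest_path} is missing"
            )
        frames.append(
            read_frame(
                fpath, fmt,
                scale=doc.get("tiff_scale"), offset=doc.get("tiff_offset"),
                timestamp=float(timestamps[i]), index=i,
            )
        )
    return ThermalRecording(
        frames=frames,
        rate_hz=rate,
        position=position,
        room_temp_c=float(doc.get("room_temp_c", 23.0)),
        humidity_pct=float(doc.get("humidity_pct", 50.0)),
        subject_id=str(doc.get("subject_id", "")),
    )
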