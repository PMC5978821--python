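"""Paired rectangular ROIs and the bilateral percentage-difference statistic.

An ROI is an axis-aligned rectangle given by its top-left (inclusive) and
bottom-right (exclusive) corner in 0-based (row, col) pixel coordinates.
The half-open convention makes width/height arithmetic exact and mirroring
an involution.

Each affected-leg ROI is paired with a size-identical counterpart on the
healthy leg obtained by reflecting its column range about the image's
vertical midline (or an explicit axis column). The asymmetry statistic is

    pct_diff = (affected_mean - healthy_mean) / affected_mean * 100

i.e. the temperature elevation of the affected side as a percentage of the
affected-side temperature. The denominator is guarded: affected-side skin
temperatures in degC are strictly positive.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import Side, ThermalFrame, ThermalRecording

__all__ = [
    "RoiLabel",
    "ROI",
    "PairedROI",
    "PairedMeasurement",
    "mirror_roi",
    "roi_frame_mean",
    "roi_recording_mean",
    "measure_pair",
    "percentage_difference",
    "write_roi_table",
    "read_roi_table",
]


class RoiLabel(str, enum.Enum):
    """The five anatomical regions measured on each leg."""

    hip = "hip"
    upper_knee = "upper_knee"
    knee = "knee"
    lower_knee = "lower_knee"
    ankle = "ankle"


@dataclass(frozen=True)
class ROI:
    """Half-open rectangle [top_left, bottom_right) on one leg."""

    top_left: tuple[int, int]
    bottom_right: tuple[int, int]
    label: RoiLabel
    leg: Side

    def __post_init__(self) -> None:
        (r0, c0), (r1, c1) = self.top_left, self.bottom_right
        if r0 < 0 or c0 < 0:
            raise ValueError("ROI corners must be non-negative")
        if r1 <= r0 or c1 <= c0:
            raise ValueError(
                f"bottom_right {self.bottom_right} must exceed top_left "
                f"{self.top_left} in both coordinates"
            )
        object.__setattr__(self, "label", RoiLabel(self.label))
        leg = Side(self.leg)
        if leg not in (Side.left, Side.right):
            raise ValueError("ROI leg must be left or right")
        object.__setattr__(self, "leg", leg)

    @property
    def height(self) -> int:
        return self.bottom_right[0] - self.top_left[0]

    @property
    def width(self) -> int:
        return self.bottom_right[1] - self.top_left[1]

    @property
    def n_pixels(self) -> int:
        return self.height * self.width

    def validate_within(self, shape: tuple[int, int]) -> None:
        rows, cols = shape
        if self.bottom_right[0] > rows or self.bottom_right[1] > cols:
            raise ValueError(
                f"ROI {self.top_left}..{self.bottom_right} exceeds image {shape}"
            )


@dataclass(frozen=True)
class PairedROI:
    """An affected-leg ROI and its mirrored, size-identical healthy reference."""

    affected: ROI
    healthy: ROI

    def __post_init__(self) -> None:
        a, h = self.affected, self.healthy
        if (a.height, a.width) != (h.height, h.width):
            raise ValueError("paired ROIs must have identical height and width")
        if a.label != h.label:
            raise ValueError("paired ROIs must share one anatomical label")
        if a.leg == h.leg:
            raise ValueError("paired ROIs must lie on opposite legs")


@dataclass(frozen=True)
class PairedMeasurement:
    """Across-frame mean temperatures of one ROI pair and their asymmetry."""

    affected_mean: float
    healthy_mean: float
    n_frames: int
    frame_indices: tuple[int, ...]
    pct_diff: float

    def __post_init__(self) -> None:
        if self.n_frames != len(self.frame_indices):
            raise ValueError("n_frames must equal len(frame_indices)")


def mirror_roi(roi: ROI, image_width: int, axis: float | None = None) -> ROI:
    """Reflect an ROI's column range about a vertical axis; rows unchanged.

    The default axis is the image midline ``image_width / 2``, mapping the
    column range ``[s, e)`` to ``[W - e, W - s)``. An explicit ``axis``
    column (e.g. the midpoint between leg centroids) may override it; the
    reflected endpoints ``2*axis - e`` and ``2*axis - s`` must land on the
    integer pixel grid and inside the image. The returned ROI swaps legs and
    preserves dimensions; mirroring twice is the identity.
    """
    a = image_width / 2 if axis is None else float(axis)
    s, e = roi.top_left[1], roi.bottom_right[1]
    ns, ne = 2 * a - e, 2 * a - s
    if abs(ns - round(ns)) > 1e-9:
        raise ValueError(f"mirror axis {a} does not map columns onto the pixel grid")
    ns, ne = int(round(ns)), int(round(ne))
    if ns < 0 or ne > image_width:
        raise ValueError(
            f"mirrored column range [{ns}, {ne}) falls outside image width {image_width}"
        )
    other = Side.right if roi.leg == Side.left else Side.left
    return ROI(
        top_left=(roi.top_left[0], ns),
        bottom_right=(roi.bottom_right[0], ne),
        label=roi.label,
        leg=other,
    )


def roi_frame_mean(frame: ThermalFrame, roi: ROI) -> float:
    """Arithmetic mean temperature over the ROI's pixels in one frame."""
    roi.validate_within(frame.shape)
    (r0, c0), (r1, c1) = roi.top_left, roi.bottom_right
    return float(frame.temps[r0:r1, c0:c1].mean())


def roi_recording_mean(
    recording: ThermalRecording, roi: ROI, frame_indices: Sequence[int]
) -> float:
    """Unweighted mean of the per-frame ROI means over the given frames."""
    if len(frame_indices) == 0:
        raise ValueError("frame_indices must be non-empty")
    n = len(recording)
    for i in frame_indices:
        if not 0 <= i < n:
            raise IndexError(f"frame index {i} out of range for {n}-frame recording")
    means = [roi_frame_mean(recording.frames[i], roi) for i in frame_indices]
    return float(np.mean(means))


def percentage_difference(affected_mean: float, healthy_mean: float) -> float:
    """Bilateral asymmetry as a percentage of the affected-side temperature.

    Returns ``(affected - healthy) / affected * 100`` at full precision;
    rounding to 2 decimal places happens only at reporting boundaries.
    """
    if affected_mean <= 0:
        raise ValueError(
            "affected-side mean must be positive degC (denominator guard); "
            f"got {affected_mean}"
        )
    return (affected_mean - healthy_mean) / affected_mean * 100.0


def measure_pair(
    recording: ThermalRecording,
    paired: PairedROI,
    frame_indices: Sequence[int],
) -> PairedMeasurement:
    """Average both ROIs of a pair over the same frame set and compare them."""
    affected = roi_recording_mean(recording, paired.affected, frame_indices)
    healthy = roi_recording_mean(recording, paired.healthy, frame_indices)
    return PairedMeasurement(
        affected_mean=affected,
        healthy_mean=healthy,
        n_frames=len(frame_indices),
        frame_indices=tuple(int(i) for i in frame_indices),
        pct_diff=percentage_difference(affected, healthy),
    )


# ---------------------------------------------------------------------------
# ROI tables (one tabular text file per subject)
# ---------------------------------------------------------------------------

_ROI_COLUMNS = ["label", "leg", "top_row", "top_col", "bottom_row", "bottom_col"]


def write_roi_table(rois: Iterable[ROI], path: str | Path) -> None:
    """Write ROIs as a TSV with columns label, leg, top/bottom corner coords."""
    rows = [
        {
            "label": r.label.value,
            "leg": r.leg.value,
            "top_row": r.top_left[0],
            "top_col": r.top_left[1],
            "bottom_row": r.bottom_right[0],
            "bottom_col": r.bottom_right[1],
        }
        for r in rois
    ]
    pd.DataFrame(rows, columns=_ROI_COLUMNS).to_csv(path, sep="\t", index=False)


def read_roi_table(path: str | Path) -> list[ROI]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_ROI_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ROI table {path} lacks columns {sorted(missing)}")
    return [
        ROI(
            top_left=(int(row.top_row), int(row.top_col)),
            bottom_right=(int(row.bottom_row), int(row.bottom_col)),
            label=RoiLabel(row.label),
            leg=Side(row.leg),
        )
        for row in df.itertuples()
    ]
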