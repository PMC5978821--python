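"""Published group-median skin temperatures used as calibration and fixtures.

These are the group median (and IQR, where defined) affected- and
healthy-leg temperatures reported by the pilot clinical study this pipeline
models, organised by presenting-complaint region, ROI, imaging position and
diagnosis group. Per-subject raw data were never published, so these medians
serve two purposes only: realistic operating ranges for the synthetic
phantom, and regression inputs for the percentage-difference statistic
(whose outputs are always recomputed, never stored here).

``position`` is ``"standing"`` or ``"sitting"``; IQR is ``None`` for
single-subject groups.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import Diagnosis, Region
from .roi import RoiLabel

__all__ = ["GroupMedians", "GROUP_MEDIANS"]


@dataclass(frozen=True)
class GroupMedians:
    region: Region
    roi: RoiLabel
    position: str
    diagnosis: Diagnosis
    n: int
    affected_median_c: float
    affected_iqr_c: float | None
    healthy_median_c: float
    healthy_iqr_c: float | None


GROUP_MEDIANS: tuple[GroupMedians, ...] = (
    GroupMedians(Region.hip_thigh, RoiLabel.upper_knee, "standing",
                 Diagnosis.soft_tissue_injury, 3, 32.01, 1.92, 31.18, 2.64),
    GroupMedians(Region.hip_thigh, RoiLabel.upper_knee, "standing",
                 Diagnosis.irritable_hip, 9, 32.77, 1.74, 32.54, 1.85),
    GroupMedians(Region.hip_thigh, RoiLabel.hip, "standing",
                 Diagnosis.soft_tissue_injury, 4, 31.93, 1.64, 31.50, 1.12),
    GroupMedians(Region.hip_thigh, RoiLabel.hip, "standing",
                 Diagnosis.irritable_hip, 8, 32.16, 2.19, 31.82, 1.60),
    GroupMedians(Region.hip_thigh, RoiLabel.upper_knee, "sitting",
                 Diagnosis.soft_tissue_injury, 1, 31.91, None, 30.65, None),
    GroupMedians(Region.hip_thigh, RoiLabel.upper_knee, "sitting",
                 Diagnosis.irritable_hip, 6, 32.99, 2.49, 32.73, 1.79),
    GroupMedians(Region.knee, RoiLabel.knee, "standing",
                 Diagnosis.soft_tissue_injury, 4, 31.87, 1.05, 31.47, 1.80),
    GroupMedians(Region.knee, RoiLabel.knee, "sitting",
                 Diagnosis.soft_tissue_injury, 6, 32.76, 1.70, 32.43, 0.99),
    GroupMedians(Region.lower_leg, RoiLabel.lower_knee, "standing",
                 Diagnosis.soft_tissue_injury, 1, 33.34, None, 32.85, None),
    GroupMedians(Region.lower_leg, RoiLabel.lower_knee, "standing",
                 Diagnosis.fracture, 3, 30.58, 2.55, 29.39, 2.08),
    GroupMedians(Region.lower_leg, RoiLabel.lower_knee, "sitting",
                 Diagnosis.soft_tissue_injury, 2, 33.97, 0.38, 33.45, 0.65),
    GroupMedians(Region.lower_leg, RoiLabel.lower_knee, "sitting",
                 Diagnosis.fracture, 4, 32.45, 3.16, 30.72, 1.92),
)
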