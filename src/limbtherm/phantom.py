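"""Synthetic leg-pair thermal phantoms, recordings and cohorts.

The phantom emulates the imaging subject: two vertical lower-limb
silhouettes, exactly mirror-symmetric about the image's vertical midline,
over a cooler background at room temperature. Skin temperature decreases
linearly from the proximal (hip/thigh) end of the leg to the distal (ankle)
end, matching the proximodistal gradient seen on real limbs. Pathology is
modelled as an additive isotropic Gaussian "hotspot" on one leg; per-pixel
sensor noise is i.i.d. Gaussian at the camera's NETD scale (0.04 degC by
default). A configurable fraction of frames in a recording is corrupted by
a large horizontal shift of the scene plus a temperature bias on the limb
pixels, emulating subject motion; corrupted frames are distinguishable only
by their content, so frame selection has to find them.

Geometry is specified fractionally (relative to the image shape) so the
same phantom renders consistently at any resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .io import (
    Diagnosis,
    ImagingPosition,
    Region,
    Side,
    SubjectRecord,
    ThermalFrame,
    ThermalRecording,
)
from .roi import ROI, RoiLabel, mirror_roi

__all__ = [
    "LegGeometry",
    "Hotspot",
    "PhantomParams",
    "GroupModel",
    "CohortSpec",
    "SyntheticSubject",
    "render_scene",
    "leg_masks",
    "phantom_rois",
    "primary_roi",
    "generate_phantom_frame",
    "generate_recording",
    "generate_cohort",
    "default_cohort_spec",
    "reference_cohort_records",
]


@dataclass(frozen=True)
class LegGeometry:
    """Fractional silhouette geometry of the left leg (right is its mirror).

    ``axis_offset_frac`` is the distance of the leg axis from the image
    midline as a fraction of image width; half-widths taper linearly from
    the proximal to the distal end (thigh wider than ankle).
    """

    top_frac: float = 0.06
    bottom_frac: float = 0.94
    axis_offset_frac: float = 0.18
    half_width_top_frac: float = 0.09
    half_width_bottom_frac: float = 0.045

    def __post_init__(self) -> None:
        if not 0 <= self.top_frac < self.bottom_frac <= 1:
            raise ValueError("leg must span a non-empty row range inside the image")
        if min(self.half_width_top_frac, self.half_width_bottom_frac) <= 0:
            raise ValueError("leg half-widths must be positive")


@dataclass(frozen=True)
class Hotspot:
    """Additive isotropic Gaussian temperature elevation on one leg."""

    leg: Side
    center: tuple[float, float]  # (row, col) in pixels
    sigma_px: float
    amplitude_c: float

    def __post_init__(self) -> None:
        if self.amplitude_c < 0:
            raise ValueError("hotspot amplitude must be >= 0")
        if self.sigma_px <= 0:
            raise ValueError("hotspot sigma must be positive")
        leg = Side(self.leg)
        if leg not in (Side.left, Side.right):
            raise ValueError("hotspot leg must be left or right")
        object.__setattr__(self, "leg", leg)


@dataclass(frozen=True)
class PhantomParams:
    """Full description of one synthetic scene.

    Defaults reproduce the study acquisition: 480x640 rasters, proximal
    (thigh) skin warmer than distal (ankle), room-temperature background,
    and sensor noise at the camera's NETD (< 40 mK).
    """

    image_shape: tuple[int, int] = (480, 640)
    geometry: LegGeometry = field(default_factory=LegGeometry)
    proximal_temp_c: float = 33.5
    distal_temp_c: float = 30.5
    background_temp_c: float = 23.0
    hotspot: Hotspot | None = None
    noise_sd_c: float = 0.04
    corrupt_frac: float = 0.0

    def __post_init__(self) -> None:
        rows, cols = self.image_shape
        if rows < 8 or cols < 8:
            raise ValueError("image must be at least 8x8 pixels")
        if self.proximal_temp_c < self.distal_temp_c:
            raise ValueError(
                "proximal temperature must be >= distal (proximodistal gradient)"
            )
        if self.noise_sd_c < 0:
            raise ValueError("noise sd must be >= 0")
        if not 0 <= self.corrupt_frac < 1:
            raise ValueError("corrupt_frac must be in [0, 1)")
        if self.hotspot is not None:
            r, c = self.hotspot.center
            if not (0 <= r < rows and 0 <= c < cols):
                raise ValueError(
                    f"hotspot center {self.hotspot.center} outside image {self.image_shape}"
                )


def leg_masks(params: PhantomParams) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (left, right) silhouette masks; right is fliplr(left) exactly."""
    rows, cols = params.image_shape
    g = params.geometry
    top = int(round(g.top_frac * rows))
    bottom = int(round(g.bottom_frac * rows))
    rr = np.arange(rows)[:, None]
    cc = np.arange(cols)[None, :]
    frac = np.clip((rr - top) / max(bottom - 1 - top, 1), 0.0, 1.0)
    hw = (
        g.half_width_top_frac
        + (g.half_width_bottom_frac - g.half_width_top_frac) * frac
    ) * cols
    axis_left = (cols - 1) / 2 - g.axis_offset_frac * cols
    left = (rr >= top) & (rr < bottom) & (np.abs(cc - axis_left) <= hw)
    right = np.fliplr(left)
    return left, right


def render_scene(params: PhantomParams, *, with_hotspot: bool = True) -> np.ndarray:
    """Noise-free temperature scene: background + gradient legs (+ hotspot)."""
    rows, cols = params.image_shape
    g = params.geometry
    top = int(round(g.top_frac * rows))
    bottom = int(round(g.bottom_frac * rows))
    left, right = leg_masks(params)
    rr = np.arange(rows)[:, None]
    frac = np.clip((rr - top) / max(bottom - 1 - top, 1), 0.0, 1.0)
    grad = params.proximal_temp_c + (params.distal_temp_c - params.proximal_temp_c) * frac
    scene = np.full(params.image_shape, params.background_temp_c, dtype=float)
    mask = left | right
    scene = np.where(mask, grad, scene)
    if with_hotspot and params.hotspot is not None:
        h = params.hotspot
        r0, c0 = h.center
        cc = np.arange(cols)[None, :]
        bump = h.amplitude_c * np.exp(
            -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * h.sigma_px**2)
        )
        leg_mask = left if h.leg == Side.left else right
        scene = scene + bump * leg_mask
    return scene


def _corrupt_scene(params: PhantomParams) -> np.ndarray:
    """Motion-corrupted variant: horizontal roll plus a bias on limb pixels."""
    scene = render_scene(params)
    left, right = leg_masks(params)
    shift = max(4, int(round(0.08 * params.image_shape[1])))
    shifted = np.roll(scene, shift, axis=1)
    shifted_mask = np.roll(left | right, shift, axis=1)
    return shifted + 2.0 * shifted_mask


def generate_phantom_frame(
    params: PhantomParams,
    rng: np.random.Generator,
    *,
    timestamp: float = 0.0,
    index: int = 0,
) -> ThermalFrame:
    """One noisy frame of the phantom scene."""
    scene = render_scene(params)
    if params.noise_sd_c > 0:
        scene = scene + rng.normal(0.0, params.noise_sd_c, size=scene.shape)
    return ThermalFrame(temps=scene, timestamp=timestamp, index=index)


def generate_recording(
    params: PhantomParams,
    duration_s: float = 20.0,
    rate_hz: float = 30.0,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    position: ImagingPosition = ImagingPosition.anterior_standing,
    subject_id: str = "phantom",
    return_truth: bool = False,
):
    """Simulate one video recording of ``floor(duration_s * rate_hz)`` frames.

    A ``corrupt_frac`` fraction of frames (rounded down, chosen by a seeded
    draw) is rendered from the motion-corrupted scene. With
    ``return_truth=True`` also returns the sorted corrupted frame indices
    (ground truth for evaluating frame selection).
    """
    if duration_s <= 0 or rate_hz <= 0:
        raise ValueError("duration and rate must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = math.floor(duration_s * rate_hz + 1e-9)
    n_corrupt = math.floor(params.corrupt_frac * n)
    corrupt_idx = (
        np.sort(rng.choice(n, size=n_corrupt, replace=False))
        if n_corrupt
        else np.empty(0, dtype=int)
    )
    corrupt_set = set(int(i) for i in corrupt_idx)
    clean = render_scene(params)
    bad = _corrupt_scene(params) if corrupt_set else None
    frames = []
    for i in range(n):
        scene = bad if i in corrupt_set else clean
        if params.noise_sd_c > 0:
            scene = scene + rng.normal(0.0, params.noise_sd_c, size=scene.shape)
        frames.append(ThermalFrame(temps=scene, timestamp=i / rate_hz, index=i))
    rec = ThermalRecording(
        frames=frames,
        rate_hz=rate_hz,
        position=position,
        room_temp_c=params.background_temp_c,
        subject_id=subject_id,
    )
    if return_truth:
        return rec, [int(i) for i in corrupt_idx]
    return rec


# ---------------------------------------------------------------------------
# Phantom ROI layout
# ---------------------------------------------------------------------------

_ROI_ORDER = [
    RoiLabel.hip,
    RoiLabel.upper_knee,
    RoiLabel.knee,
    RoiLabel.lower_knee,
    RoiLabel.ankle,
]

_PRIMARY_ROI = {
    Region.hip_thigh: RoiLabel.hip,
    Region.knee: RoiLabel.knee,
    Region.lower_leg: RoiLabel.lower_knee,
    Region.ankle: RoiLabel.ankle,
}


def primary_roi(region: Region) -> RoiLabel:
    """The single ROI most directly over a presenting-complaint region."""
    return _PRIMARY_ROI[Region(region)]


def phantom_rois(params: PhantomParams, leg: Side = Side.left) -> dict[RoiLabel, ROI]:
    """Five anatomical ROIs laid out proximodistally along one phantom leg.

    The leg's row span is split into five equal bands (hip at the top,
    ankle at the bottom); each ROI covers the central 60% of its band in
    height and 70% of the local leg width, so it sits fully inside the
    silhouette.
    """
    rows, cols = params.image_shape
    g = params.geometry
    top = int(round(g.top_frac * rows))
    bottom = int(round(g.bottom_frac * rows))
    span = bottom - top
    axis_left = (cols - 1) / 2 - g.axis_offset_frac * cols
    out: dict[RoiLabel, ROI] = {}
    for i, label in enumerate(_ROI_ORDER):
        b0 = top + i * span / 5
        b1 = top + (i + 1) * span / 5
        rc = (b0 + b1) / 2
        h = max(2, int(round(0.6 * (b1 - b0))))
        r0 = int(round(rc - h / 2))
        frac = (rc - top) / max(span - 1, 1)
        hw = (
            g.half_width_top_frac
            + (g.half_width_bottom_frac - g.half_width_top_frac) * frac
        ) * cols
        w = max(2, int(round(2 * 0.7 * hw)))
        c0 = int(round(axis_left - w / 2))
        roi = ROI(
            top_left=(r0, c0),
            bottom_right=(r0 + h, c0 + w),
            label=label,
            leg=Side.left,
        )
        if leg == Side.right:
            roi = mirror_roi(roi, cols)
        roi.validate_within(params.image_shape)
        out[label] = roi
    return out


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupModel:
    """Per-diagnosis simulation model: group size, hotspot magnitude, regions."""

    n: int
    delta_t_mean_c: float
    delta_t_sd_c: float
    region_probs: Mapping[Region, float]
    trauma_prob: float = 0.5
    weight_bearing_prob: float = 0.6

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("group size must be >= 0")
        if self.delta_t_mean_c < 0 or self.delta_t_sd_c < 0:
            raise ValueError("hotspot distribution parameters must be >= 0")
        total = sum(self.region_probs.values())
        if self.region_probs and not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValueError("region probabilities must sum to 1")


@dataclass(frozen=True)
class CohortSpec:
    """A whole synthetic study: groups, base phantom, recording geometry, seed.

    Cohort recordings default to a reduced geometry (1 s at 30 Hz, 120x160
    rasters) so that multi-subject simulations stay desk-scale; single
    recordings via :func:`generate_recording` keep the full acquisition
    defaults.
    """

    groups: Mapping[Diagnosis, GroupModel]
    base_params: PhantomParams = field(
        default_factory=lambda: PhantomParams(image_shape=(120, 160), corrupt_frac=0.1)
    )
    duration_s: float = 1.0
    rate_hz: float = 30.0
    #: SD of the per-subject whole-leg baseline temperature shift (degC),
    #: emulating inter-subject variation in resting skin temperature.
    baseline_sd_c: float = 0.8
    seed: int = 0


@dataclass
class SyntheticSubject:
    """One simulated subject: clinical record, ground truth, data."""

    record: SubjectRecord
    hotspot_delta_t_c: float
    rois: dict[RoiLabel, ROI]  # on the affected leg
    recordings: dict[ImagingPosition, ThermalRecording]


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The study-shaped default cohort: 30 subjects in five diagnosis groups.

    Group sizes follow the study cohort (13 soft-tissue injuries, 9
    irritable hips, 3 fractures, 4 other, 1 undiagnosed). Hotspot magnitudes
    are ordered fracture > soft-tissue injury > irritable hip, calibrated so
    the resulting percentage differences land in the observed 0.7-5.3% range.
    """
    groups = {
        Diagnosis.soft_tissue_injury: GroupModel(
            n=13, delta_t_mean_c=1.2, delta_t_sd_c=0.3,
            region_probs={
                Region.hip_thigh: 0.30, Region.knee: 0.30,
                Region.lower_leg: 0.30, Region.ankle: 0.10,
            },
            trauma_prob=0.7, weight_bearing_prob=0.6,
        ),
        Diagnosis.irritable_hip: GroupModel(
            n=9, delta_t_mean_c=0.4, delta_t_sd_c=0.15,
            region_probs={Region.hip_thigh: 1.0},
            trauma_prob=0.1, weight_bearing_prob=0.5,
        ),
        Diagnosis.fracture: GroupModel(
            n=3, delta_t_mean_c=2.5, delta_t_sd_c=0.4,
            region_probs={Region.lower_leg: 0.8, Region.ankle: 0.2},
            trauma_prob=0.9, weight_bearing_prob=0.3,
        ),
        Diagnosis.other: GroupModel(
            n=4, delta_t_mean_c=1.0, delta_t_sd_c=0.3,
            region_probs={
                Region.hip_thigh: 0.25, Region.knee: 0.25,
                Region.lower_leg: 0.25, Region.ankle: 0.25,
            },
        ),
        Diagnosis.unknown: GroupModel(
            n=1, delta_t_mean_c=0.8, delta_t_sd_c=0.3,
            region_probs={
                Region.hip_thigh: 0.25, Region.knee: 0.25,
                Region.lower_leg: 0.25, Region.ankle: 0.25,
            },
        ),
    }
    return CohortSpec(groups=groups, seed=seed, **overrides)


_COHORT_POSITIONS = (ImagingPosition.anterior_sitting, ImagingPosition.anterior_standing)


def generate_cohort(spec: CohortSpec) -> list[SyntheticSubject]:
    """Simulate every subject of a cohort, with recordings in both positions.

    Each subject draws a complaint region, affected side and hotspot
    magnitude from their diagnosis group's model; the hotspot sits at the
    centre of the primary ROI of the complaint region on the affected leg.
    Fully deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    base = spec.base_params
    left_rois = phantom_rois(base, Side.left)
    subjects: list[SyntheticSubject] = []
    sid = 0
    for diagnosis, gm in spec.groups.items():
        regions = list(gm.region_probs.keys())
        probs = np.array([gm.region_probs[r] for r in regions], dtype=float)
        for _ in range(gm.n):
            region = regions[int(rng.choice(len(regions), p=probs))] if regions else Region.knee
            side = Side.left if rng.random() < 0.6 else Side.right
            delta_t = max(0.0, float(rng.normal(gm.delta_t_mean_c, gm.delta_t_sd_c)))
            age = float(np.clip(rng.normal(5.2, 3.0), 0.5, 14.9))
            record = SubjectRecord(
                subject_id=f"S{sid:03d}",
                age_years=round(age, 1),
                sex="female" if rng.random() < 0.33 else "male",
                height_cm=round(85 + 5.5 * age + rng.normal(0, 4), 1),
                weight_kg=round(10 + 2.6 * age + rng.normal(0, 2), 1),
                body_temp_c=round(float(rng.normal(36.2, 0.4)), 1),
                affected_side=side,
                complaint_region=region,
                onset_hours=round(float(rng.uniform(2, 48)), 1),
                diagnosis=diagnosis,
                trauma=bool(rng.random() < gm.trauma_prob),
                weight_bearing=bool(rng.random() < gm.weight_bearing_prob),
            )
            rois = (
                dict(left_rois)
                if side == Side.left
                else {lb: mirror_roi(r, base.image_shape[1]) for lb, r in left_rois.items()}
            )
            target = rois[primary_roi(region)]
            center = (
                (target.top_left[0] + target.bottom_right[0]) / 2,
                (target.top_left[1] + target.bottom_right[1]) / 2,
            )
            baseline = float(rng.normal(0.0, spec.baseline_sd_c))
            params = replace(
                base,
                proximal_temp_c=base.proximal_temp_c + baseline,
                distal_temp_c=base.distal_temp_c + baseline,
                hotspot=Hotspot(
                    leg=side,
                    center=center,
                    sigma_px=0.4 * target.height,
                    amplitude_c=delta_t,
                ) if delta_t > 0 else None,
            )
            recordings = {
                pos: generate_recording(
                    params, spec.duration_s, spec.rate_hz,
                    rng=rng, position=pos, subject_id=record.subject_id,
                )
                for pos in _COHORT_POSITIONS
            }
            subjects.append(
                SyntheticSubject(
                    record=record,
                    hotspot_delta_t_c=delta_t,
                    rois=rois,
                    recordings=recordings,
                )
            )
            sid += 1
    return subjects


def reference_cohort_records() -> list[SubjectRecord]:
    """A deterministic 30-subject table matching the study's reported marginals.

    Category counts: 16/14 trauma yes/no, 17/13 weight-bearing yes/no,
    11 right / 18 left / 1 bilateral, complaint regions 13 hip-thigh /
    6 knee / 8 lower-leg / 3 ankle, diagnoses 13 soft-tissue / 9 irritable
    hip / 3 fracture / 4 other / 1 unknown. The bilateral subject carries an
    "other" diagnosis (a myositis-like case). The joint assignment of
    categories across subjects is an arbitrary deterministic interleaving:
    only the marginal counts are meaningful.
    """
    diagnoses = (
        [Diagnosis.soft_tissue_injury] * 13
        + [Diagnosis.irritable_hip] * 9
        + [Diagnosis.fracture] * 3
        + [Diagnosis.other] * 4
        + [Diagnosis.unknown] * 1
    )
    sides = [Side.left] * 18 + [Side.right] * 11
    sides.insert(25, Side.both)  # index 25 is an "other" subject
    regions = (
        [Region.hip_thigh] * 13
        + [Region.knee] * 6
        + [Region.lower_leg] * 8
        + [Region.ankle] * 3
    )
    trauma = [True] * 16 + [False] * 14
    weight_bearing = [True] * 17 + [False] * 13
    records = []
    for i in range(30):
        age = 1.0 + (i % 13)
        records.append(
            SubjectRecord(
                subject_id=f"R{i:03d}",
                age_years=age,
                sex="male" if i % 3 else "female",
                height_cm=round(85 + 5.5 * age, 1),
                weight_kg=round(10 + 2.6 * age, 1),
                body_temp_c=36.2,
                affected_side=sides[i],
                complaint_region=regions[i],
                onset_hours=6.0 + (i % 40),
                diagnosis=diagnoses[i],
                trauma=trauma[i],
                weight_bearing=weight_bearing[i],
            )
        )
    return records
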