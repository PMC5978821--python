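"""Cohort-level exclusions, complaint-region -> ROI mapping, and summaries.

Study design rules implemented here:

* Exclusions — subjects are excluded when symptom onset was more than 48 h
  before imaging, when aged 15 or over, when both legs are involved (no
  healthy internal reference remains), or when no diagnosis could be
  established. Each exclusion carries a machine-readable reason code.
* Region relevance — only ROIs over the presenting-complaint region enter
  the group analysis: hip/thigh pain -> hip and upper-knee ROIs; knee pain
  -> knee ROI; lower-leg pain -> lower-knee ROI; ankle pain -> ankle ROI.
* Group summaries — subgroup temperature distributions are skewed at these
  sample sizes, so groups are summarised by the median (with IQR) of the
  per-subject affected and healthy means, and the group percentage
  difference is the asymmetry statistic applied to the two medians (not the
  median of per-subject percentages). IQR uses linear interpolation between
  order statistics and is reported as absent for single-subject groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import Diagnosis, ImagingPosition, Region, Side, SubjectRecord
from .roi import PairedMeasurement, RoiLabel, percentage_difference

__all__ = [
    "EXCLUSION_MAX_ONSET_HOURS",
    "EXCLUSION_MAX_AGE_YEARS",
    "GroupSummary",
    "apply_exclusions",
    "relevant_rois",
    "summarize_group",
    "group_summaries",
    "descriptive_summary",
    "format_group_table",
]

EXCLUSION_MAX_ONSET_HOURS = 48.0
EXCLUSION_MAX_AGE_YEARS = 15.0

#: The three diagnosis groups reported in group summaries.
NAMED_GROUPS = (Diagnosis.soft_tissue_injury, Diagnosis.irritable_hip, Diagnosis.fracture)

_RELEVANT = {
    Region.hip_thigh: (RoiLabel.hip, RoiLabel.upper_knee),
    Region.knee: (RoiLabel.knee,),
    Region.lower_leg: (RoiLabel.lower_knee,),
    Region.ankle: (RoiLabel.ankle,),
}


@dataclass(frozen=True)
class GroupSummary:
    """One group-summary row: medians, IQRs and their percentage difference."""

    diagnosis: Diagnosis
    region: Region
    roi: RoiLabel
    position: ImagingPosition
    n: int
    median_affected_c: float
    iqr_affected_c: float | None
    median_healthy_c: float
    iqr_healthy_c: float | None
    pct_diff: float


def apply_exclusions(
    cohort: Iterable[SubjectRecord],
) -> tuple[list[SubjectRecord], list[tuple[SubjectRecord, tuple[str, ...]]]]:
    """Split a cohort into included subjects and excluded subjects with reasons.

    Reason codes: ``onset_over_48h``, ``age_ge_15``, ``bilateral``,
    ``unknown_diagnosis``. A subject may carry several.
    """
    included, excluded = [], []
    for rec in cohort:
        reasons = []
        if rec.onset_hours > EXCLUSION_MAX_ONSET_HOURS:
            reasons.append("onset_over_48h")
        if rec.age_years >= EXCLUSION_MAX_AGE_YEARS:
            reasons.append("age_ge_15")
        if rec.affected_side == Side.both:
            reasons.append("bilateral")
        if rec.diagnosis == Diagnosis.unknown:
            reasons.append("unknown_diagnosis")
        if reasons:
            excluded.append((rec, tuple(reasons)))
        else:
            included.append(rec)
    return included, excluded


def relevant_rois(region: Region) -> tuple[RoiLabel, ...]:
    """ROIs that enter the analysis for a presenting-complaint region."""
    try:
        return _RELEVANT[Region(region)]
    except (KeyError, ValueError) as err:
        raise ValueError(f"unknown complaint region: {region!r}") from err


def _median_iqr(values: Sequence[float]) -> tuple[float, float | None]:
    arr = np.asarray(values, dtype=float)
    med = float(np.median(arr))
    if arr.size == 1:
        return med, None
    q25, q75 = np.percentile(arr, [25, 75], method="linear")
    return med, float(q75 - q25)


def summarize_group(
    measurements: Sequence[PairedMeasurement],
    *,
    diagnosis: Diagnosis,
    region: Region,
    roi: RoiLabel,
    position: ImagingPosition,
) -> GroupSummary:
    """Summarise one (diagnosis, region, ROI, position) subgroup.

    Medians/IQRs are taken across subjects separately for the affected and
    healthy means; the group percentage difference applies the asymmetry
    statistic to the two medians. Single-subject groups report no IQR.
    """
    if not measurements:
        raise ValueError("cannot summarise an empty group")
    med_a, iqr_a = _median_iqr([m.affected_mean for m in measurements])
    med_h, iqr_h = _median_iqr([m.healthy_mean for m in measurements])
    return GroupSummary(
        diagnosis=Diagnosis(diagnosis),
        region=Region(region),
        roi=RoiLabel(roi),
        position=ImagingPosition(position),
        n=len(measurements),
        median_affected_c=med_a,
        iqr_affected_c=iqr_a,
        median_healthy_c=med_h,
        iqr_healthy_c=iqr_h,
        pct_diff=percentage_difference(med_a, med_h),
    )


def group_summaries(
    measurements: pd.DataFrame, subjects: pd.DataFrame
) -> pd.DataFrame:
    """Build the group-summary table from tidy measurement + subject tables.

    ``measurements`` needs columns subject_id, position, roi, affected_mean,
    healthy_mean; ``subjects`` the SubjectRecord fields. Exclusion rules are
    applied, only region-relevant ROIs are kept, and only the three named
    diagnosis groups are reported (subjects with "other" diagnoses remain in
    descriptive summaries but have no group row). A subject lacking a
    recording in some position simply contributes nothing to that row.
    """
    records = [
        SubjectRecord(
            subject_id=str(r.subject_id),
            age_years=float(r.age_years),
            sex=str(r.sex),
            height_cm=float(r.height_cm),
            weight_kg=float(r.weight_kg),
            body_temp_c=float(r.body_temp_c),
            affected_side=Side(r.affected_side),
            complaint_region=Region(r.complaint_region),
            onset_hours=float(r.onset_hours),
            diagnosis=Diagnosis(r.diagnosis),
            trauma=bool(r.trauma),
            weight_bearing=bool(r.weight_bearing),
        )
        for r in subjects.itertuples()
    ]
    included, _ = apply_exclusions(records)
    meta = {
        rec.subject_id: rec for rec in included if rec.diagnosis in NAMED_GROUPS
    }
    rows = []
    df = measurements[measurements["subject_id"].isin(meta)]
    for (sid, pos, roi), grp in df.groupby(["subject_id", "position", "roi"], sort=False):
        rec = meta[sid]
        if RoiLabel(roi) not in relevant_rois(rec.complaint_region):
            continue
        for r in grp.itertuples():
            rows.append(
                {
                    "diagnosis": rec.diagnosis.value,
                    "region": rec.complaint_region.value,
                    "roi": roi,
                    "position": pos,
                    "subject_id": sid,
                    "affected_mean": float(r.affected_mean),
                    "healthy_mean": float(r.healthy_mean),
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=[
                "region", "roi", "position", "diagnosis", "n",
                "median_affected_c", "iqr_affected_c",
                "median_healthy_c", "iqr_healthy_c", "pct_diff",
            ]
        )
    tidy = pd.DataFrame(rows)
    out = []
    for (region, roi, pos, diag), grp in tidy.groupby(
        ["region", "roi", "position", "diagnosis"], sort=True
    ):
        med_a, iqr_a = _median_iqr(grp["affected_mean"].to_numpy())
        med_h, iqr_h = _median_iqr(grp["healthy_mean"].to_numpy())
        out.append(
            {
                "region": region,
                "roi": roi,
                "position": pos,
                "diagnosis": diag,
                "n": len(grp),
                "median_affected_c": med_a,
                "iqr_affected_c": iqr_a,
                "median_healthy_c": med_h,
                "iqr_healthy_c": iqr_h,
                "pct_diff": percentage_difference(med_a, med_h),
            }
        )
    return pd.DataFrame(out)


_DESCRIPTIVE_CATEGORIES: list[tuple[str, list[str]]] = [
    ("trauma", ["yes", "no"]),
    ("weight_bearing", ["yes", "no"]),
    ("side", [s.value for s in (Side.right, Side.left, Side.both)]),
    ("region", [r.value for r in Region]),
    ("diagnosis", [d.value for d in Diagnosis]),
]


def descriptive_summary(cohort: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Counts and percentages of presenting-complaint categories.

    One row per (category, level): trauma, weight-bearing, affected side,
    complaint region and diagnosis, with percentages of the cohort size to
    one decimal place.
    """
    if not cohort:
        raise ValueError("cannot summarise an empty cohort")
    n = len(cohort)

    def level_of(rec: SubjectRecord, category: str) -> str:
        if category == "trauma":
            return "yes" if rec.trauma else "no"
        if category == "weight_bearing":
            return "yes" if rec.weight_bearing else "no"
        if category == "side":
            return rec.affected_side.value
        if category == "region":
            return rec.complaint_region.value
        return rec.diagnosis.value

    rows = []
    for category, levels in _DESCRIPTIVE_CATEGORIES:
        counts = {lv: 0 for lv in levels}
        for rec in cohort:
            counts[level_of(rec, category)] += 1
        for lv in levels:
            rows.append(
                {
                    "category": category,
                    "level": lv,
                    "count": counts[lv],
                    "pct": round(100.0 * counts[lv] / n, 1),
                }
            )
    return pd.DataFrame(rows)


def format_group_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Render a group-summary table to the reporting precision.

    Temperatures appear as ``median (IQR)`` with 2 decimal places and
    ``(n/a)`` for absent IQRs; percentage differences are rounded to 2
    decimal places.
    """
    def fmt(med: float, iqr: float | None) -> str:
        iqr_s = "n/a" if iqr is None or pd.isna(iqr) else f"{iqr:.2f}"
        return f"{med:.2f} ({iqr_s})"

    rows = []
    for r in summaries.itertuples():
        rows.append(
            {
                "region": r.region,
                "roi": r.roi,
                "position": r.position,
                "diagnosis": r.diagnosis,
                "n": r.n,
                "affected": fmt(r.median_affected_c, r.iqr_affected_c),
                "healthy": fmt(r.median_healthy_c, r.iqr_healthy_c),
                "pct_diff": f"{r.pct_diff:.2f}",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["region", "roi", "position", "diagnosis", "n", "affected", "healthy", "pct_diff"],
    )
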