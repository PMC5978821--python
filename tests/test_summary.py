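"""Exclusion rules, region->ROI mapping, group and descriptive summaries."""

import numpy as np
import pandas as pd
import pytest

from limbtherm import (
    Diagnosis,
    ImagingPosition,
    PairedMeasurement,
    Region,
    RoiLabel,
    Side,
    SubjectRecord,
    apply_exclusions,
    descriptive_summary,
    group_summaries,
    percentage_difference,
    reference_cohort_records,
    relevant_rois,
    summarize_group,
)


def subject(**overrides):
    defaults = dict(
        subject_id="S000", age_years=5.0, sex="male", height_cm=110.0,
        weight_kg=20.0, body_temp_c=36.2, affected_side=Side.left,
        complaint_region=Region.knee, onset_hours=12.0,
        diagnosis=Diagnosis.soft_tissue_injury, trauma=True, weight_bearing=True,
    )
    defaults.update(overrides)
    return SubjectRecord(**defaults)


def measurement(affected, healthy, n_frames=20):
    return PairedMeasurement(
        affected_mean=affected, healthy_mean=healthy, n_frames=n_frames,
        frame_indices=tuple(range(n_frames)),
        pct_diff=percentage_difference(affected, healthy),
    )


class TestExclusions:
    @pytest.mark.parametrize(
        "overrides,reason",
        [
            ({"affected_side": Side.both}, "bilateral"),
            ({"diagnosis": Diagnosis.unknown}, "unknown_diagnosis"),
            ({"onset_hours": 49.0}, "onset_over_48h"),
            ({"age_years": 15.0}, "age_ge_15"),
        ],
    )
    def test_each_rule_excludes_with_reason(self, overrides, reason):
        included, excluded = apply_exclusions([subject(**overrides)])
        assert included == []
        assert excluded[0][1] == (reason,)

    def test_boundary_subject_included(self):
        # 14.9 years, 47 h onset, unilateral, diagnosed: all criteria satisfied
        included, excluded = apply_exclusions(
            [subject(age_years=14.9, onset_hours=47.0)]
        )
        assert len(included) == 1 and not excluded

    def test_reference_cohort_retains_28(self):
        included, excluded = apply_exclusions(reference_cohort_records())
        assert len(included) == 28
        reasons = sorted(r for _, rs in excluded for r in rs)
        assert reasons == ["bilateral", "unknown_diagnosis"]

    def test_multiple_reasons_accumulate(self):
        _, excluded = apply_exclusions(
            [subject(age_years=16.0, onset_hours=72.0)]
        )
        assert set(excluded[0][1]) == {"onset_over_48h", "age_ge_15"}


class TestRelevantRois:
    @pytest.mark.parametrize(
        "region,expected",
        [
            (Region.hip_thigh, (RoiLabel.hip, RoiLabel.upper_knee)),
            (Region.knee, (RoiLabel.knee,)),
            (Region.lower_leg, (RoiLabel.lower_knee,)),
            (Region.ankle, (RoiLabel.ankle,)),
        ],
    )
    def test_region_to_roi_mapping(self, region, expected):
        assert relevant_rois(region) == expected

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError, match="unknown complaint region"):
            relevant_rois("shoulder")


class TestSummarizeGroup:
    def keys(self):
        return dict(
            diagnosis=Diagnosis.soft_tissue_injury, region=Region.hip_thigh,
            roi=RoiLabel.upper_knee, position=ImagingPosition.anterior_sitting,
        )

    def test_single_subject_group(self):
        s = summarize_group([measurement(31.91, 30.65)], **self.keys())
        assert s.n == 1
        assert s.median_affected_c == 31.91
        assert s.median_healthy_c == 30.65
        assert s.iqr_affected_c is None and s.iqr_healthy_c is None
        assert round(s.pct_diff, 2) == 3.95

    def test_median_of_three(self):
        ms = [measurement(a, a - 0.5) for a in (30.0, 31.0, 32.0)]
        s = summarize_group(ms, **self.keys())
        assert s.median_affected_c == 31.0

    def test_median_iqr_match_sort_based_oracle(self, rng):
        for _ in range(25):
            vals = 29.0 + 5.0 * rng.random(9)
            ms = [measurement(float(v), float(v) - 1.0) for v in vals]
            s = summarize_group(ms, **self.keys())
            srt = np.sort(vals)
            # oracle: linear interpolation between order statistics, by hand
            def quantile(q):
                pos = q * (len(srt) - 1)
                lo, frac = int(np.floor(pos)), pos - int(np.floor(pos))
                return srt[lo] * (1 - frac) + srt[min(lo + 1, len(srt) - 1)] * frac

            assert s.median_affected_c == pytest.approx(quantile(0.5), rel=1e-12)
            assert s.iqr_affected_c == pytest.approx(
                quantile(0.75) - quantile(0.25), rel=1e-12
            )

    def test_invariant_to_subject_order(self, rng):
        vals = 29.0 + 5.0 * rng.random(8)
        ms = [measurement(float(v), float(v) - 0.7) for v in vals]
        a = summarize_group(ms, **self.keys())
        b = summarize_group(ms[::-1], **self.keys())
        assert a == b

    def test_group_pct_from_medians_not_median_of_pcts(self):
        # constructed so the two conventions disagree
        ms = [measurement(30.0, 29.0), measurement(40.0, 38.0), measurement(35.0, 30.0)]
        s = summarize_group(ms, **self.keys())
        assert s.pct_diff == pytest.approx(percentage_difference(35.0, 30.0))
        median_of_pcts = float(np.median([m.pct_diff for m in ms]))
        assert s.pct_diff != pytest.approx(median_of_pcts)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            summarize_group([], **self.keys())


class TestDescriptiveSummary:
    def test_reference_cohort_percentages(self):
        df = descriptive_summary(reference_cohort_records())
        def cell(category, level):
            row = df[(df.category == category) & (df.level == level)].iloc[0]
            return row["count"], row["pct"]

        assert cell("diagnosis", "soft_tissue_injury") == (13, 43.3)
        assert cell("side", "left") == (18, 60.0)
        assert cell("side", "right") == (11, 36.7)
        assert cell("trauma", "yes") == (16, 53.3)
        assert cell("weight_bearing", "no") == (13, 43.3)
        assert cell("region", "hip_thigh") == (13, 43.3)

    def test_single_subject_cohort_at_100_percent(self):
        df = descriptive_summary([subject()])
        nonzero = df[df["count"] > 0]
        assert (nonzero["pct"] == 100.0).all()

    def test_percentages_sum_to_100_within_rounding(self):
        df = descriptive_summary(reference_cohort_records())
        for _, grp in df.groupby("category"):
            assert round(grp["pct"].sum(), 1) == pytest.approx(100.0, abs=0.1)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            descriptive_summary([])


class TestGroupSummariesTable:
    def test_irrelevant_rois_and_unnamed_groups_dropped(self):
        subjects = pd.DataFrame(
            [
                vars_of(subject(subject_id="A", complaint_region=Region.knee)),
                vars_of(subject(subject_id="B", complaint_region=Region.knee,
                                diagnosis=Diagnosis.other)),
            ]
        )
        measurements = pd.DataFrame(
            [
                row("A", "knee", 32.0, 31.0),
                row("A", "ankle", 31.0, 31.0),   # irrelevant ROI for knee pain
                row("B", "knee", 33.0, 30.0),    # "other" diagnosis: no group row
            ]
        )
        out = group_summaries(measurements, subjects)
        assert len(out) == 1
        r = out.iloc[0]
        assert (r["roi"], r["diagnosis"], r["n"]) == ("knee", "soft_tissue_injury", 1)
        assert r["pct_diff"] == pytest.approx(percentage_difference(32.0, 31.0))


def vars_of(rec: SubjectRecord) -> dict:
    return {
        "subject_id": rec.subject_id, "age_years": rec.age_years, "sex": rec.sex,
        "height_cm": rec.height_cm, "weight_kg": rec.weight_kg,
        "body_temp_c": rec.body_temp_c, "affected_side": rec.affected_side.value,
        "complaint_region": rec.complaint_region.value,
        "onset_hours": rec.onset_hours, "diagnosis": rec.diagnosis.value,
        "trauma": rec.trauma, "weight_bearing": rec.weight_bearing,
    }


def row(sid, roi, affected, healthy):
    return {
        "subject_id": sid, "position": "anterior_sitting", "roi": roi,
        "leg": "left", "affected_mean": affected, "healthy_mean": healthy,
        "pct_diff": percentage_difference(affected, healthy), "n_frames": 20,
    }
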