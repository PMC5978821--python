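"""ROI geometry, averaging oracles, and the percentage-difference statistic."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from limbtherm import (
    ROI,
    Hotspot,
    ImagingPosition,
    PairedROI,
    RoiLabel,
    Side,
    ThermalFrame,
    ThermalRecording,
    generate_recording,
    measure_pair,
    mirror_roi,
    percentage_difference,
    phantom_rois,
    roi_frame_mean,
    roi_recording_mean,
)
from limbtherm.phantom import render_scene
from limbtherm.roi import read_roi_table, write_roi_table


def frame_of(temps):
    return ThermalFrame(temps=np.asarray(temps, dtype=float))


def make_roi(r0, c0, r1, c1, label=RoiLabel.knee, leg=Side.left):
    return ROI(top_left=(r0, c0), bottom_right=(r1, c1), label=label, leg=leg)


@st.composite
def roi_and_width(draw):
    width = draw(st.integers(8, 640))
    c0 = draw(st.integers(0, width - 2))
    c1 = draw(st.integers(c0 + 1, width))
    r0 = draw(st.integers(0, 50))
    r1 = draw(st.integers(r0 + 1, 60))
    return make_roi(r0, c0, r1, c1), width


class TestMirror:
    def test_reflection_arithmetic(self):
        roi = make_roi(10, 100, 20, 150)
        m = mirror_roi(roi, 640)
        assert (m.top_left[1], m.bottom_right[1]) == (490, 540)
        assert (m.top_left[0], m.bottom_right[0]) == (10, 20)
        assert m.leg == Side.right and m.label == roi.label

    @given(roi_and_width())
    def test_mirror_is_an_involution_preserving_size(self, rw):
        roi, width = rw
        m = mirror_roi(roi, width)
        assert (m.height, m.width) == (roi.height, roi.width)
        assert mirror_roi(m, width) == roi

    def test_off_centre_axis_out_of_bounds_rejected(self):
        roi = make_roi(0, 0, 5, 10)
        with pytest.raises(ValueError, match="outside image"):
            mirror_roi(roi, 64, axis=2.0)

    def test_mirrored_mean_equal_on_symmetric_phantom(self, small_params, small_rois):
        scene = render_scene(small_params)
        frame = ThermalFrame(temps=scene)
        for roi in small_rois.values():
            m = mirror_roi(roi, small_params.image_shape[1])
            assert roi_frame_mean(frame, roi) == roi_frame_mean(frame, m)


class TestRoiValidation:
    def test_degenerate_rectangle_rejected(self):
        with pytest.raises(ValueError):
            make_roi(5, 5, 5, 10)

    def test_out_of_bounds_roi_rejected_at_measurement(self):
        frame = frame_of(np.zeros((10, 10)) + 30.0)
        with pytest.raises(ValueError, match="exceeds image"):
            roi_frame_mean(frame, make_roi(0, 0, 12, 5))

    def test_paired_roi_must_match_size_label_and_oppose_legs(self):
        a = make_roi(0, 0, 4, 4)
        with pytest.raises(ValueError, match="height and width"):
            PairedROI(a, make_roi(0, 10, 4, 15, leg=Side.right))
        with pytest.raises(ValueError, match="label"):
            PairedROI(a, make_roi(0, 10, 4, 14, label=RoiLabel.hip, leg=Side.right))
        with pytest.raises(ValueError, match="opposite"):
            PairedROI(a, make_roi(0, 10, 4, 14))

    def test_roi_table_round_trip(self, tmp_path, small_rois):
        path = tmp_path / "rois.tsv"
        write_roi_table(small_rois.values(), path)
        assert read_roi_table(path) == list(small_rois.values())


class TestAveraging:
    def test_forced_arithmetic_2x2(self):
        frame = frame_of([[30.0, 31.0], [32.0, 33.0]])
        assert roi_frame_mean(frame, make_roi(0, 0, 2, 2)) == 31.5

    def test_uniform_frame_any_roi(self):
        frame = frame_of(np.full((20, 20), 31.0))
        assert roi_frame_mean(frame, make_roi(3, 4, 9, 17)) == 31.0

    def test_frame_mean_matches_brute_force_loop(self, rng):
        for _ in range(20):
            temps = 23.0 + 12.0 * rng.random((30, 40))
            r0, c0 = rng.integers(0, 20, 2)
            h, w = rng.integers(1, 10, 2)
            roi = make_roi(int(r0), int(c0), int(r0 + h), int(c0 + w))
            total, count = 0.0, 0
            for r in range(roi.top_left[0], roi.bottom_right[0]):
                for c in range(roi.top_left[1], roi.bottom_right[1]):
                    total += temps[r, c]
                    count += 1
            assert roi_frame_mean(frame_of(temps), roi) == pytest.approx(
                total / count, rel=1e-12
            )

    def test_recording_mean_is_mean_of_frame_means(self):
        stacks = [np.full((4, 4), t) for t in (30.0, 31.0, 32.0)]
        frames = [ThermalFrame(temps=s, index=i) for i, s in enumerate(stacks)]
        rec = ThermalRecording(frames=frames, rate_hz=10,
                               position=ImagingPosition.anterior_sitting)
        assert roi_recording_mean(rec, make_roi(0, 0, 4, 4), [0, 1, 2]) == 31.0

    def test_empty_index_list_rejected(self, clean_recording):
        with pytest.raises(ValueError, match="non-empty"):
            roi_recording_mean(clean_recording, make_roi(0, 0, 4, 4), [])

    def test_bad_frame_index_rejected(self, clean_recording):
        with pytest.raises(IndexError):
            roi_recording_mean(clean_recording, make_roi(0, 0, 4, 4), [999])


class TestPercentageDifference:
    @pytest.mark.parametrize(
        "affected,healthy,expected",
        [
            (32.01, 31.18, 2.59),   # soft tissue injury, upper knee, standing
            (30.58, 29.39, 3.89),   # fracture, lower knee, standing
            (32.45, 30.72, 5.33),   # fracture, lower knee, sitting
            (31.0, 31.0, 0.00),
        ],
    )
    def test_known_values_at_two_decimals(self, affected, healthy, expected):
        assert round(percentage_difference(affected, healthy), 2) == expected

    def test_denominator_guard(self):
        with pytest.raises(ValueError, match="positive"):
            percentage_difference(0.0, 30.0)
        with pytest.raises(ValueError, match="positive"):
            percentage_difference(-1.0, 30.0)

    @given(
        affected=st.floats(25.0, 40.0),
        d1=st.floats(-3.0, 3.0),
        d2=st.floats(-3.0, 3.0),
    )
    def test_strictly_increasing_in_gap_and_zero_iff_equal(self, affected, d1, d2):
        p1 = percentage_difference(affected, affected - d1)
        p2 = percentage_difference(affected, affected - d2)
        if d1 - d2 > 1e-6:  # gaps below float precision cannot separate
            assert p1 > p2
        assert percentage_difference(affected, affected) == 0.0


class TestMeasurePair:
    def test_symmetric_phantom_pct_diff_exactly_zero(self, small_params, small_rois):
        rec = generate_recording(replace(small_params, noise_sd_c=0.0), 0.5, 10, seed=0)
        for roi in small_rois.values():
            paired = PairedROI(roi, mirror_roi(roi, rec.shape[1]))
            m = measure_pair(rec, paired, list(range(len(rec))))
            assert m.pct_diff == 0.0

    def test_hotspot_elevation_recovered_noise_free(self, small_params, small_rois):
        roi = small_rois[RoiLabel.lower_knee]
        r0 = (roi.top_left[0] + roi.bottom_right[0]) / 2
        c0 = (roi.top_left[1] + roi.bottom_right[1]) / 2
        sigma, amp = 4.0, 1.0
        params = replace(
            small_params,
            hotspot=Hotspot(Side.left, center=(r0, c0), sigma_px=sigma, amplitude_c=amp),
        )
        rec = generate_recording(params, 0.5, 10, seed=0)
        paired = PairedROI(roi, mirror_roi(roi, rec.shape[1]))
        m = measure_pair(rec, paired, list(range(len(rec))))
        # oracle: numerical mean of the Gaussian over the ROI grid
        rr, cc = np.meshgrid(
            np.arange(roi.top_left[0], roi.bottom_right[0]),
            np.arange(roi.top_left[1], roi.bottom_right[1]),
            indexing="ij",
        )
        expected = float(
            np.mean(amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2)))
        )
        assert m.affected_mean - m.healthy_mean == pytest.approx(expected, rel=1e-9)

    def test_swapping_roles_flips_sign_per_asymmetric_denominator(
        self, small_params, small_rois
    ):
        roi = small_rois[RoiLabel.knee]
        params = replace(
            small_params,
            hotspot=Hotspot(
                Side.left,
                center=(
                    (roi.top_left[0] + roi.bottom_right[0]) / 2,
                    (roi.top_left[1] + roi.bottom_right[1]) / 2,
                ),
                sigma_px=4.0,
                amplitude_c=1.0,
            ),
        )
        rec = generate_recording(params, 0.5, 10, seed=0)
        mirrored = mirror_roi(roi, rec.shape[1])
        idx = list(range(len(rec)))
        fwd = measure_pair(rec, PairedROI(roi, mirrored), idx)
        rev = measure_pair(rec, PairedROI(mirrored, roi), idx)
        # (h - a)/h * 100 == -(a - h)/h * 100: sign flips, magnitude rescales
        assert rev.pct_diff == pytest.approx(
            -(fwd.affected_mean - fwd.healthy_mean) / fwd.healthy_mean * 100.0,
            rel=1e-12,
        )
        assert fwd.pct_diff > 0 > rev.pct_diff
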