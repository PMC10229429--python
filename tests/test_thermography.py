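"""Body segmentation, pose, ROI placement and trace extraction."""

import numpy as np
import pytest

from _oracles import roi_mean_bruteforce
from uihkit import synth, thermography as tg
from uihkit.core import BodyPose, DiskROI, ThermalStack, TimeSeries


def ellipse_mask(shape, center, a, b, theta_deg):
    rows, cols = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    th = np.deg2rad(theta_deg)
    dr, dc = rows - center[0], cols - center[1]
    ax = dr * np.cos(th) + dc * np.sin(th)
    pe = -dr * np.sin(th) + dc * np.cos(th)
    return (ax / a) ** 2 + (pe / b) ** 2 <= 1.0


class TestSegmentBody:
    def test_uniform_frame_gives_empty_mask(self):
        frame = np.full((20, 20), 22.0)
        assert not tg.segment_body(frame, 4.0, ambient_estimate=22.0).any()

    def test_three_pixel_blob_recovered_exactly(self):
        frame = np.full((15, 15), 22.0)
        px = [(3, 4), (3, 5), (4, 4)]
        for r, c in px:
            frame[r, c] = 30.0
        mask = tg.segment_body(frame, 4.0, ambient_estimate=22.0)
        assert sorted(map(tuple, np.argwhere(mask))) == sorted(px)

    def test_largest_component_wins(self):
        frame = np.full((20, 20), 22.0)
        frame[2:4, 2:4] = 30.0  # 4 px
        frame[10:14, 10:14] = 30.0  # 16 px
        mask = tg.segment_body(frame, 4.0, ambient_estimate=22.0)
        assert mask[11, 11] and not mask[2, 2]

    def test_rendered_ellipse_area_within_5pct(self):
        truth = ellipse_mask((64, 80), (32, 40), 25, 12, 0)
        frame = np.where(truth, 34.0, 22.0)
        mask = tg.segment_body(frame, 4.0, ambient_estimate=22.0)
        assert abs(mask.sum() - truth.sum()) / truth.sum() < 0.05


class TestEstimatePose:
    def test_rectangle_centroid_and_axis(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[10:15, 5:26] = True  # long side along columns
        pose = tg.estimate_pose(mask, 1.0)
        assert pose.centroid == pytest.approx((12.0, 15.0))
        assert abs(pose.anterior_unit[1]) == pytest.approx(1.0, abs=1e-9)

    def test_single_pixel_mask_is_degenerate(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[5, 5] = True
        with pytest.raises(ValueError, match="degenerate"):
            tg.estimate_pose(mask, 1.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="no body"):
            tg.estimate_pose(np.zeros((5, 5), dtype=bool), 1.0)

    @pytest.mark.parametrize("theta", [0.0, 20.0, 45.0, 70.0])
    def test_ellipse_orientation_recovered_within_2_degrees(self, theta):
        mask = ellipse_mask((90, 90), (45, 45), 30, 12, theta)
        pose = tg.estimate_pose(mask, 1.0)
        got = np.rad2deg(np.arctan2(pose.anterior_unit[1], pose.anterior_unit[0]))
        diff = abs((got - theta + 90) % 180 - 90)
        assert diff < 2.0

    def test_warmer_end_resolves_anterior(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:25, 12:18] = True
        frame = np.full((30, 30), 22.0)
        frame[mask] = 33.0
        frame[5:10, 12:18] = 36.0  # head end is warmer
        pose = tg.estimate_pose(mask, 1.0, frame=frame)
        assert pose.anterior_unit[0] < 0  # toward decreasing rows


class TestLocateBatRoi:
    def _pose(self, centroid, anterior, length):
        mask = np.ones((100, 100), dtype=bool)
        return BodyPose(centroid, np.asarray(anterior, float), length, mask, 1.0)

    def test_quarter_length_anterior_offset(self):
        pose = self._pose((50.0, 50.0), (-1.0, 0.0), 80.0)
        roi = tg.locate_bat_roi(pose)
        assert roi.center == pytest.approx((30.0, 50.0))
        assert roi.radius_mm == 3.0

    def test_zero_fraction_is_identity(self):
        pose = self._pose((50.0, 50.0), (0.0, 1.0), 80.0)
        roi = tg.locate_bat_roi(pose, fraction=0.0)
        assert roi.center == pytest.approx((50.0, 50.0))

    def test_out_of_frame_center_clipped_and_flagged(self):
        pose = self._pose((10.0, 50.0), (-1.0, 0.0), 80.0)
        roi = tg.locate_bat_roi(pose, frame_shape=(100, 100))
        assert roi.clipped and roi.center[0] == 0.0


class TestRoiMean:
    def test_uniform_frame(self):
        frame = np.full((20, 20), 35.0)
        assert tg.roi_mean(frame, DiskROI((10, 10), 3.0), 1.0) == pytest.approx(35.0)

    def test_two_by_two_patch(self):
        frame = np.zeros((10, 10))
        frame[0, 0], frame[0, 1], frame[1, 0], frame[1, 1] = 30, 32, 34, 36
        roi = DiskROI((0.5, 0.5), 0.8)  # includes exactly the 4 corner pixels
        assert tg.roi_mean(frame, roi, 1.0) == pytest.approx(33.0)

    def test_matches_bruteforce_on_random_frames(self, rng):
        for _ in range(50):
            frame = rng.normal(30, 3, (rng.integers(8, 16), rng.integers(8, 16)))
            center = (rng.uniform(0, frame.shape[0]), rng.uniform(0, frame.shape[1]))
            radius = rng.uniform(0.5, 5.0)
            px = rng.uniform(0.4, 2.0)
            expected = roi_mean_bruteforce(frame, center, radius, px)
            if expected is None:
                with pytest.raises(ValueError):
                    tg.roi_mean(frame, DiskROI(center, radius), px)
            else:
                assert tg.roi_mean(frame, DiskROI(center, radius), px) == pytest.approx(
                    expected, abs=1e-12
                )

    def test_roi_outside_frame_rejected(self):
        frame = np.zeros((10, 10))
        with pytest.raises(ValueError, match="outside"):
            tg.roi_mean(frame, DiskROI((50.0, 50.0), 2.0), 1.0)


class TestTailRoiMean:
    def test_uniform_tail_value(self):
        frame = np.full((40, 40), 28.0)
        v = tg.tail_roi_mean(frame, (5, 20), np.array([1.0, 0.0]), 1.0)
        assert v == pytest.approx(28.0)

    def test_disk_in_background_returns_ambient(self):
        frame = np.full((40, 40), 22.0)
        frame[0:10, :] = 30.0  # body far from the tail ROI
        v = tg.tail_roi_mean(frame, (25, 20), np.array([1.0, 0.0]), 1.0)
        assert v == pytest.approx(22.0)


class TestExtractTrace:
    def test_uniform_frames_give_their_values(self):
        frames = np.stack([np.full((8, 8), v) for v in (30.0, 31.0, 32.0)])
        stack = ThermalStack(frames, [0.0, 1.0, 2.0], 1.0)
        tr = tg.extract_trace(stack, DiskROI((4, 4), 2.0))
        assert np.allclose(tr.values, [30, 31, 32])

    def test_empty_stack_rejected(self):
        stack = ThermalStack(np.empty((0, 8, 8)), np.empty(0), 1.0)
        with pytest.raises(ValueError, match="empty"):
            tg.extract_trace(stack, DiskROI((4, 4), 2.0))

    def test_matches_frame_by_frame_manual_calls(self, rng):
        frames = rng.normal(28, 2, (5, 12, 12))
        stack = ThermalStack(frames, np.arange(5.0), 1.0)
        roi = DiskROI((6.0, 6.0), 2.5)
        tr = tg.extract_trace(stack, roi)
        manual = [tg.roi_mean(f, roi, 1.0) for f in stack.frames]
        assert np.allclose(tr.values, manual, atol=1e-12)

    def test_none_roi_gives_nan(self):
        frames = np.zeros((3, 8, 8))
        stack = ThermalStack(frames, np.arange(3.0), 1.0)
        tr = tg.extract_trace(stack, [DiskROI((4, 4), 2.0), None, DiskROI((4, 4), 2.0)])
        assert np.isnan(tr.values[1]) and not np.isnan(tr.values[0])


class TestLowpass:
    def test_constant_trace_unchanged(self):
        tr = TimeSeries(np.arange(0, 50, 0.5), np.full(100, 36.0), "degC")
        assert np.allclose(tg.lowpass(tr, 0.1).values, 36.0, atol=1e-9)

    def test_high_frequency_sinusoid_attenuated(self):
        t = np.arange(0, 100, 0.5)  # fs = 2 Hz
        tr = TimeSeries(t, np.sin(2 * np.pi * 0.8 * t))
        out = tg.lowpass(tr, 0.1)
        assert np.abs(out.values[40:-40]).max() < 0.1  # >= 90% attenuation

    def test_dc_preserved_under_noise(self, rng):
        t = np.arange(0, 100, 0.5)
        tr = TimeSeries(t, 30.0 + rng.normal(0, 0.5, t.size))
        out = tg.lowpass(tr, 0.1)
        assert out.values.mean() == pytest.approx(tr.values.mean(), abs=1e-2)

    def test_cutoff_at_nyquist_rejected(self):
        tr = TimeSeries(np.arange(0, 10, 0.5), np.zeros(20))
        with pytest.raises(ValueError, match="Nyquist"):
            tg.lowpass(tr, 1.0)

    def test_irregular_sampling_rejected(self):
        tr = TimeSeries([0.0, 1.0, 3.0, 7.0], np.zeros(4))
        with pytest.raises(ValueError, match="uniform"):
            tg.lowpass(tr, 0.1)


class TestPipelineRecovery:
    def test_noiseless_video_trace_recovered_within_005(self):
        trace, _ = synth.dip_trace(2.0, sample_interval_s=4.0)
        stack, truth = synth.render_thermal_video(
            {"T_BAT": trace}, frame_rate_hz=None, noise_sd=0.0, seed=0
        )
        head = tuple(truth["head_mm"][0])
        measured = tg.bat_trace(stack, head_hint=head)
        assert np.abs(measured.values - truth["t_bat"]).max() < 0.05

    def test_tracked_roi_within_2mm_of_truth(self):
        trace, _ = synth.dip_trace(3.0, sample_interval_s=8.0)
        geo = synth.BodyGeometry(drift_mm_per_s=(0.002, 0.003))
        stack, truth = synth.render_thermal_video(
            {"T_BAT": trace}, geometry=geo, frame_rate_hz=None, noise_sd=0.1, seed=4
        )
        rois, _ = tg.track_bat(stack, head_hint=tuple(truth["head_mm"][0]))
        centers = np.array([r.center for r in rois])
        err = np.hypot(*(centers - truth["bat_center_mm"]).T)
        assert (err <= 2.0).mean() >= 0.95
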