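"""Measurement pipeline: registration, ROIs, correction, metrics, NEBD."""

import numpy as np
import pytest

from follicle_cnd.analysis import (MetricUndefinedError, ROISet,
                                   background_from_fixtures, correct_channels,
                                   define_rois, detect_nebd, extract_traces,
                                   nebd_histogram, register_stack,
                                   rois_from_ground_truth, summarize_traces,
                                   time_below_baseline,
                                   time_to_fraction_of_peak,
                                   time_to_fractional_decline,
                                   time_to_near_minimum)
from follicle_cnd.imaging import FollicleScene, render_timelapse
from follicle_cnd.sensor import CAMPFIRE_M, ratio_from_concentration


def _noise_free(scene, **extra):
    return FollicleScene(**{**scene.__dict__, "shot_noise": False,
                            "read_noise_frac": 0.0, "jitter_sd": 0.0,
                            **extra})


class TestCorrectChannels:
    def test_worked_example_alpha_23(self):
        cfp, yfp, ratio = correct_channels(200.0, 446.0, 0.0, 0.0, alpha=0.23)
        assert yfp == pytest.approx(400.0)
        assert ratio == pytest.approx(0.5)

    def test_alpha_zero_identity(self):
        _, _, ratio = correct_channels(120.0, 300.0, 0.0, 0.0, alpha=0.0)
        assert ratio == pytest.approx(120.0 / 300.0)

    def test_zero_signal(self):
        cfp, _, ratio = correct_channels(50.0, 400.0, 50.0, 0.0, alpha=0.23)
        assert cfp == 0.0
        assert ratio == 0.0

    def test_low_yfp_flagged_not_raised(self):
        _, yfp, ratio = correct_channels(100.0, 5.0, 0.0, 0.0, alpha=0.23,
                                         floor=10.0)
        assert yfp < 10.0
        assert np.isnan(ratio)

    def test_order_of_operations_matters(self):
        """Overlap-before-background is a different (wrong) pipeline."""
        cfp_m, yfp_m, cfp_bg, yfp_bg, alpha = 300.0, 500.0, 80.0, 90.0, 0.23
        _, _, ratio = correct_channels(cfp_m, yfp_m, cfp_bg, yfp_bg, alpha)
        wrong_yfp = (yfp_m - alpha * cfp_m) - yfp_bg
        wrong_ratio = (cfp_m - cfp_bg) / wrong_yfp
        assert ratio != pytest.approx(wrong_ratio, rel=1e-6)


class TestDefineRois:
    def test_band_widths_in_pixels(self):
        rois = define_rois((512, 512), (256, 256), follicle_radius=175.0,
                           oocyte_radius=37.5, nucleus_radius=15.0,
                           pixel_size=0.8)
        m = rois["outer_mural"]
        ys, xs = np.nonzero(m)
        rr = np.hypot(ys - 256, xs - 256)
        width_px = rr.max() - rr.min()
        assert width_px == pytest.approx(40.0 / 0.8, abs=1.5)

    def test_masks_disjoint(self):
        rois = define_rois((256, 256), (128, 128), follicle_radius=150.0,
                           oocyte_radius=37.5, nucleus_radius=15.0,
                           pixel_size=1.5)
        total = sum(m.astype(int) for m in rois.masks.values())
        assert total.max() == 1

    def test_oocyte_outside_follicle_rejected(self):
        with pytest.raises(ValueError):
            define_rois((256, 256), (128, 128), follicle_radius=50.0,
                        oocyte_radius=60.0, nucleus_radius=10.0,
                        pixel_size=1.0)

    def test_too_small_follicle_rejected(self):
        with pytest.raises(ValueError):
            define_rois((256, 256), (128, 128), follicle_radius=80.0,
                        oocyte_radius=37.5, nucleus_radius=15.0,
                        pixel_size=1.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            ROISet(masks={"oocyte": np.zeros((8, 8), dtype=bool)})


class TestRegistration:
    def test_zero_shift_stack(self, small_scene, short_wt_traces):
        scene = _noise_free(small_scene)
        stack = render_timelapse(scene, short_wt_traces, CAMPFIRE_M,
                                 times=np.arange(-10.0, 20.0), noise=False)
        _, shifts = register_stack(stack)
        assert np.all(shifts == 0)

    def test_recovers_seeded_jitter(self, small_scene, short_wt_traces):
        scene = FollicleScene(**{**small_scene.__dict__, "jitter_sd": 1.5})
        stack = render_timelapse(scene, short_wt_traces, CAMPFIRE_M,
                                 times=np.arange(-10.0, 30.0))
        _, shifts = register_stack(stack)
        # registration is relative to frame 0, which carries its own
        # jitter offset; the correction undoes the relative displacement
        rel = stack.true_shifts - stack.true_shifts[0]
        err = shifts + rel
        rms = np.sqrt((err**2).sum(axis=1).mean())
        assert rms < 0.5

    def test_single_frame_rejected(self, small_scene, short_wt_traces):
        stack = render_timelapse(small_scene, short_wt_traces, CAMPFIRE_M,
                                 times=np.array([0.0]))
        with pytest.raises(ValueError):
            register_stack(stack)


class TestExtractTraces:
    def test_closed_loop_noise_free(self, small_scene, short_wt_traces):
        scene = _noise_free(small_scene, bleedthrough_alpha=0.0)
        stack = render_timelapse(scene, short_wt_traces, CAMPFIRE_M,
                                 noise=False)
        rois = rois_from_ground_truth(stack)
        traces = extract_traces(stack, rois, alpha=0.0)
        for roi, region in (("outer_mural", "mural"), ("cumulus", "cumulus"),
                            ("oocyte", "oocyte")):
            got = traces.ratio[roi]
            want = stack.true_ratios[region]
            assert np.max(np.abs(got / want - 1)) < 0.005

    def test_bleedthrough_corrected_closed_loop(self, small_scene,
                                                short_wt_traces):
        scene = _noise_free(small_scene)  # alpha = 0.23 injected
        stack = render_timelapse(scene, short_wt_traces, CAMPFIRE_M,
                                 noise=False)
        rois = rois_from_ground_truth(stack)
        traces = extract_traces(stack, rois, alpha=0.23)
        got = traces.ratio["oocyte"]
        want = stack.true_ratios["oocyte"]
        assert np.max(np.abs(got / want - 1)) < 0.005

    def test_background_roi_as_signal_is_flagged(self, small_scene,
                                                 short_wt_traces):
        scene = _noise_free(small_scene)
        stack = render_timelapse(scene, short_wt_traces, CAMPFIRE_M,
                                 noise=False)
        masks = dict(stack.masks)
        masks["fake_signal"] = masks.pop("oocyte")
        # use the background region's pixels as a signal ROI
        masks["fake_signal"] = stack.masks["background"]
        masks["background"] = stack.masks["background"]
        # ROISet forbids overlap, so pass fixture backgrounds instead
        rois = ROISet(masks={"fake_signal": stack.masks["background"]},
                      provenance="user-supplied")
        bgs = {"fake_signal": (scene.cfp_background, scene.yfp_background)}
        traces = extract_traces(stack, rois, alpha=0.23, background=bgs)
        assert not traces.qc_ok["fake_signal"].any()

    def test_fixture_backgrounds_from_uninjected_follicles(self, small_scene,
                                                           short_wt_traces):
        scene = _noise_free(small_scene)
        stack = render_timelapse(scene, short_wt_traces, CAMPFIRE_M,
                                 noise=False)
        rois = rois_from_ground_truth(stack)
        fixtures = []
        for k in range(5):
            fs = FollicleScene(**{**scene.__dict__, "uninjected": True,
                                  "seed": 100 + k})
            fixtures.append(render_timelapse(fs, short_wt_traces, CAMPFIRE_M,
                                             times=np.arange(-10.0, 0.0)))
        bgs = background_from_fixtures(fixtures, rois)
        traces = extract_traces(stack, rois, background=bgs)
        want = stack.true_ratios["oocyte"]
        assert np.max(np.abs(traces.ratio["oocyte"] / want - 1)) < 0.01


class TestLandmarkMetrics:
    def _ramp(self):
        t = np.arange(-10.0, 31.0)
        y = np.interp(t, [0.0, 10.0], [1.0, 2.0], left=1.0, right=2.0)
        return t, y

    def test_half_rise_linear_interpolation(self):
        t, y = self._ramp()
        assert time_to_fraction_of_peak(t, y, 0.5) == pytest.approx(5.0)

    def test_flat_trace_undefined(self):
        t = np.arange(-10.0, 31.0)
        with pytest.raises(MetricUndefinedError):
            time_to_fraction_of_peak(t, np.ones_like(t), 0.5)

    def test_quarter_decline_linear(self):
        t = np.arange(-10.0, 101.0)
        y = np.interp(t, [0.0, 100.0], [2.0, 1.0], left=2.0)
        assert time_to_fractional_decline(t, y, 0.25) == pytest.approx(25.0)

    def test_rising_trace_decline_undefined(self):
        t, y = self._ramp()
        with pytest.raises(MetricUndefinedError):
            time_to_fractional_decline(t, y, 0.25)

    def test_time_below_baseline(self):
        t = np.arange(-10.0, 121.0)
        y = np.interp(t, [0.0, 30.0, 90.0], [1.0, 2.0, 0.5],
                      left=1.0, right=0.5)
        got = time_below_baseline(t, y)
        assert got == pytest.approx(70.0, abs=0.01)

    def test_time_to_near_minimum(self):
        t = np.arange(-10.0, 101.0)
        y = np.interp(t, [0.0, 100.0], [2.0, 1.0], left=2.0)
        assert time_to_near_minimum(t, y, 0.05) == pytest.approx(95.0)

    def test_metric_stability_under_sampling(self, wt_traces):
        from follicle_cnd import simulate
        coarse = simulate(t_end=60.0, dt_out=1.0)
        fine = simulate(t_end=60.0, dt_out=0.2)
        for region in ("mural", "cumulus", "oocyte"):
            r_c = np.asarray(ratio_from_concentration(
                coarse.series("cAMP", region), CAMPFIRE_M))
            r_f = np.asarray(ratio_from_concentration(
                fine.series("cAMP", region), CAMPFIRE_M))
            t_c = time_to_fraction_of_peak(coarse.t, r_c, 0.5)
            t_f = time_to_fraction_of_peak(fine.t, r_f, 0.5)
            assert abs(t_c - t_f) < 0.5


class TestDetectNebd:
    def _stack_with_nebd(self, scene, traces, nebd, seed=0, noise=True):
        s = FollicleScene(**{**scene.__dict__, "nebd_time": nebd,
                             "seed": seed})
        times = np.arange(-10.0, 60.0)
        return render_timelapse(s, traces, CAMPFIRE_M, times=times,
                                noise=noise)

    def test_detects_at_truth(self, small_scene, short_wt_traces):
        stack = self._stack_with_nebd(small_scene, short_wt_traces, 25.0,
                                      noise=False)
        rois = rois_from_ground_truth(stack)
        got = detect_nebd(stack, rois)
        assert got == pytest.approx(25.0, abs=1.0)

    def test_no_nebd_returns_none(self, small_scene, short_wt_traces):
        stack = self._stack_with_nebd(small_scene, short_wt_traces, None,
                                      noise=False)
        rois = rois_from_ground_truth(stack)
        assert detect_nebd(stack, rois) is None

    def test_noisy_replicates_within_one_frame(self, small_scene,
                                               short_wt_traces):
        hits = 0
        n_rep = 20
        for k in range(n_rep):
            stack = self._stack_with_nebd(small_scene, short_wt_traces, 25.0,
                                          seed=k)
            rois = rois_from_ground_truth(stack)
            got = detect_nebd(stack, rois)
            if got is not None and abs(got - 25.0) <= 1.0:
                hits += 1
        assert hits >= 19

    def test_missing_nucleus_mask_rejected(self, small_scene,
                                           short_wt_traces):
        stack = self._stack_with_nebd(small_scene, short_wt_traces, 25.0,
                                      noise=False)
        rois = ROISet(masks={"oocyte": stack.masks["oocyte"]})
        with pytest.raises(ValueError):
            detect_nebd(stack, rois)


class TestSummaries:
    def test_identical_traces_zero_sem(self):
        t = np.arange(10.0)
        y = np.sin(t)
        df = summarize_traces([(t, y)] * 4)
        assert np.allclose(df["sem"], 0.0)

    def test_two_point_sem(self):
        t = np.array([0.0, 1.0])
        df = summarize_traces([(t, np.array([1.0, 1.0])),
                               (t, np.array([3.0, 3.0]))])
        assert np.allclose(df["mean"], 2.0)
        assert np.allclose(df["sem"], 1.0)

    def test_single_trace_rejected(self):
        with pytest.raises(MetricUndefinedError):
            summarize_traces([(np.arange(3.0), np.arange(3.0))])

    def test_nebd_binning(self):
        df = nebd_histogram([130.0, 140.0, 200.0], bin_width=15.0)
        lookup = {(a, b): c for a, b, c in
                  zip(df["bin_start"], df["bin_end"], df["count"])}
        assert lookup[(120.0, 135.0)] == 1
        assert lookup[(135.0, 150.0)] == 1
        assert lookup[(195.0, 210.0)] == 1
        assert df["count"].sum() == 3
        assert df["cumulative_pct"].iloc[-1] == pytest.approx(100.0)
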