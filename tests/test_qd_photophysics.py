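"""Detection, blinking maps, brightness, profile fits, group statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linear_sum_assignment

from qdsted.errors import (
    DegenerateInputError,
    FitError,
    InputError,
    InsufficientDataError,
)
from qdsted.imaging_model import PSFModel, ScanConfig, render_psf
from qdsted.qd_photophysics import (
    BlinkMap,
    analyze_qd,
    blink_map_for_qd,
    blinking_pixel_ratio,
    compare_groups,
    compute_blink_map,
    detect_qds,
    fit_double_lorentzian,
    fit_line_profile,
    integrated_brightness,
    ratio_pct,
    relative_change_pct,
    resolution_vs_power,
)
from qdsted.sted_processing import compute_stedsub
from qdsted.synthetic_data import BlinkingModel, QDField, generate_qd_field, simulate_acquisition


class TestDetect:
    def test_blank_image_gives_empty_list(self):
        assert detect_qds(np.zeros((32, 32))) == []

    def test_recall_and_precision_on_bright_field(self):
        """All 50 well-separated simulated QDs are found within 1 px of the
        ground truth (optimal assignment), with no false positives."""
        cfg = ScanConfig(30.0, (334, 334), 20.0, 1)
        field = generate_qd_field(
            50, cfg, min_separation_nm=700.0, seed=5, photon_rate_per_us=5.0,
            edge_margin_nm=400.0,
        )
        stack = simulate_acquisition(
            field, cfg, blinking=None, seed=6, channels=("STED", "STEDonly"),
            keep_line_stack=False,
        )
        sub = compute_stedsub(stack.channels["STED"], stack.channels["STEDonly"])
        variance = stack.channels["STED"] + stack.channels["STEDonly"]
        records = detect_qds(sub, min_distance_px=5, variance_image=variance)
        assert len(records) == 50
        det = np.array([r.center_px for r in records])
        truth = np.column_stack(
            [field.positions_nm[:, 1] / 30.0 - 0.5, field.positions_nm[:, 0] / 30.0 - 0.5]
        )
        cost = np.hypot(
            det[:, None, 0] - truth[None, :, 0], det[:, None, 1] - truth[None, :, 1]
        )
        ri, ci = linear_sum_assignment(cost)
        assert cost[ri, ci].max() <= 1.0

    def test_unresolved_pair_detected_as_one(self):
        cfg = ScanConfig(30.0, (41, 41), 20.0, 1)
        c = cfg.fov_nm[0] / 2
        field = QDField(
            positions_nm=np.array([[c - 50, c], [c + 50, c]]),
            photon_rate_per_us=5.0,
            multiplicity=1,
        )
        stack = simulate_acquisition(
            field, cfg, blinking=None, seed=1, channels=("confocal",), keep_line_stack=False
        )
        img = stack.channels["confocal"]
        records = detect_qds(img, min_distance_px=5, variance_image=img)
        assert len(records) == 1


class TestBlinkMap:
    def test_roi_equal_to_prediction_all_on(self):
        pred = render_psf(
            PSFModel("lorentzian", fwhm_nm=65), ScanConfig(30.0, (11, 11), 20.0), (165.0, 165.0)
        ) * 100
        bmap = compute_blink_map(pred, pred)
        assert bmap.on_mask[bmap.considered_mask].all()
        assert blinking_pixel_ratio(bmap) == 0.0

    def test_zero_roi_fully_off(self):
        pred = np.full((7, 7), 10.0)
        bmap = compute_blink_map(np.zeros((7, 7)), pred)
        assert blinking_pixel_ratio(bmap) == 1.0

    def test_zero_prediction_rejected(self):
        with pytest.raises(DegenerateInputError):
            compute_blink_map(np.ones((5, 5)), np.zeros((5, 5)))

    def test_counting_three_off_of_ten(self):
        pred = np.zeros((3, 4))
        pred[0, :] = 100.0
        pred[1, :] = 100.0
        pred[2, :2] = 100.0
        roi = np.full((3, 4), 100.0)
        roi[0, :3] = 0.0
        bmap = compute_blink_map(roi, pred)
        assert bmap.considered_mask.sum() == 10
        assert blinking_pixel_ratio(bmap) == pytest.approx(0.3)

    @given(scale=st.floats(0.1, 50.0))
    @settings(max_examples=20, deadline=None)
    def test_ratio_invariant_under_joint_scaling(self, scale):
        rng = np.random.default_rng(0)
        pred = render_psf(
            PSFModel("lorentzian", fwhm_nm=65), ScanConfig(30.0, (11, 11), 20.0), (165.0, 165.0)
        ) * 80
        roi = rng.poisson(pred * 0.6).astype(float)
        base = blinking_pixel_ratio(compute_blink_map(roi, pred))
        scaled = blinking_pixel_ratio(compute_blink_map(roi * scale, pred * scale))
        assert base == scaled

    def test_on_mask_subset_enforced(self):
        with pytest.raises(InputError):
            BlinkMap(
                roi_counts=np.zeros((2, 2)),
                on_mask=np.ones((2, 2), dtype=bool),
                considered_mask=np.zeros((2, 2), dtype=bool),
            )

    def test_nonblinking_qd_has_low_false_off_rate(self):
        """Static emitters at realistic counts misclassify few pixels OFF."""
        cfg = ScanConfig(30.0, (21, 21), 20.0, 10)
        c = cfg.fov_nm[0] / 2
        field = QDField(positions_nm=np.array([[c, c]]), photon_rate_per_us=1.0, multiplicity=1)
        ratios = []
        for s in range(30):
            stack = simulate_acquisition(
                field, cfg, blinking=None, seed=s, channels=("STED", "STEDonly")
            )
            sub = compute_stedsub(stack.channels["STED"], stack.channels["STEDonly"])
            bmap = blink_map_for_qd(sub, (10.0, 10.0), 30.0)
            ratios.append(blinking_pixel_ratio(bmap))
        assert np.mean(ratios) <= 0.05

    def test_blinking_ratio_tracks_off_occupancy(self):
        """With symmetric dwell times and fast line repeats, the measured
        blinking ratio grows with the OFF occupancy (monotone in tau_off)."""
        cfg = ScanConfig(30.0, (21, 21), 200.0, 1, flyback_time_us=(333 - 21) * 200.0)
        c = cfg.fov_nm[0] / 2
        field = QDField(positions_nm=np.array([[c, c]]), photon_rate_per_us=1.0, multiplicity=1)
        means = []
        for tau_off in (0.1, 0.4, 1.2):
            blink = BlinkingModel(tau_on_ms=0.4, tau_off_ms=tau_off, suppression_factor=1.0)
            ratios = []
            for s in range(25):
                stack = simulate_acquisition(
                    field, cfg, blinking=blink, seed=s, channels=("STED", "STEDonly")
                )
                sub = compute_stedsub(stack.channels["STED"], stack.channels["STEDonly"])
                ratios.append(
                    blinking_pixel_ratio(blink_map_for_qd(sub, (10.0, 10.0), 30.0))
                )
            means.append(np.mean(ratios))
        assert means[0] < means[1] < means[2]


class TestBrightness:
    def make_map(self, shape, considered):
        return BlinkMap(
            roi_counts=np.zeros(shape), on_mask=considered & False, considered_mask=considered
        )

    def test_zero_roi_gives_zero(self):
        considered = np.ones((5, 5), dtype=bool)
        assert integrated_brightness(np.zeros((5, 5)), self.make_map((5, 5), considered)) == 0.0

    def test_uniform_roi_with_background(self):
        considered = np.zeros((5, 5), dtype=bool)
        considered[1:4, 1:4] = True
        roi = np.full((5, 5), 10.0)
        bmap = self.make_map((5, 5), considered)
        assert integrated_brightness(roi, bmap, background_per_px=1.0) == pytest.approx(81.0)

    def test_brightness_linear_in_photon_rate(self):
        cfg = ScanConfig(30.0, (21, 21), 20.0, 10)
        c = cfg.fov_nm[0] / 2
        values = []
        for rate in (0.5, 1.0, 2.0):
            field = QDField(positions_nm=np.array([[c, c]]), photon_rate_per_us=rate, multiplicity=1)
            per_seed = []
            for s in range(15):
                stack = simulate_acquisition(
                    field, cfg, blinking=None, seed=s, channels=("STED", "STEDonly")
                )
                sub = compute_stedsub(stack.channels["STED"], stack.channels["STEDonly"])
                bmap = blink_map_for_qd(sub, (10.0, 10.0), 30.0)
                per_seed.append(integrated_brightness(sub, bmap))
            values.append(np.mean(per_seed))
        assert values[1] / values[0] == pytest.approx(2.0, rel=0.1)
        assert values[2] / values[1] == pytest.approx(2.0, rel=0.1)


class TestLineProfileFit:
    def test_exact_lorentzian_recovered(self):
        x = np.linspace(-300, 300, 41)
        y = 80.0 / (1 + 4 * (x - 12.0) ** 2 / 65.0**2)
        fit = fit_line_profile(x, y, model="lorentzian")
        assert fit.fwhm_nm == pytest.approx(65.0, rel=1e-6)
        assert fit.center_nm == pytest.approx(12.0, abs=1e-4)
        assert fit.residual < 1e-8

    def test_gaussian_with_offset_recovered(self):
        x = np.linspace(-300, 300, 41)
        y = 50.0 * np.exp(-4 * np.log(2) * x**2 / 120.0**2) + 5.0
        fit = fit_line_profile(x, y, model="gaussian", with_offset=True)
        assert fit.offset == pytest.approx(5.0, abs=1e-6)
        assert fit.fwhm_nm == pytest.approx(120.0, rel=1e-6)

    def test_too_few_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_line_profile([0, 1, 2, 3], [1, 2, 1, 0])

    def test_flat_profile_fails(self):
        x = np.linspace(0, 100, 11)
        with pytest.raises(FitError):
            fit_line_profile(x, np.ones_like(x))

    def test_double_lorentzian_components_recovered(self):
        x = np.linspace(-400, 400, 81)
        y = (
            60 / (1 + 4 * (x + 120) ** 2 / 70.0**2)
            + 40 / (1 + 4 * (x - 150) ** 2 / 90.0**2)
        )
        left, right = fit_double_lorentzian(x, y)
        assert left.center_nm == pytest.approx(-120, abs=1.0)
        assert right.center_nm == pytest.approx(150, abs=1.0)
        assert left.fwhm_nm == pytest.approx(70, rel=0.02)
        assert right.fwhm_nm == pytest.approx(90, rel=0.02)

    def test_simulated_stedsub_fwhm_within_ten_percent(self):
        px = 30.0
        cfg = ScanConfig(px, (41, 41), 20.0, 10)
        c = cfg.fov_nm[0] / 2
        field = QDField(positions_nm=np.array([[c, c]]), photon_rate_per_us=1.0, multiplicity=1)
        fwhms = []
        for s in range(50):
            stack = simulate_acquisition(
                field, cfg, sted_fwhm_nm=65.0, blinking=None, seed=s,
                channels=("STED", "STEDonly"),
            )
            sub = compute_stedsub(stack.channels["STED"], stack.channels["STEDonly"])
            x = (np.arange(41) + 0.5) * px
            fwhms.append(fit_line_profile(x, sub[20], with_offset=True).fwhm_nm)
        assert np.mean(fwhms) == pytest.approx(65.0, rel=0.10)


class TestResolutionVsPower:
    def sweep_images(self, powers, seed=0):
        from qdsted.imaging_model import effective_sted_fwhm

        px = 25.0
        cfg = ScanConfig(px, (201, 201), 20.0, 5)
        field = generate_qd_field(
            15, cfg, min_separation_nm=700.0, seed=seed, photon_rate_per_us=4.0,
            edge_margin_nm=400.0,
        )
        images = {}
        for p in powers:
            if p == 0:
                stack = simulate_acquisition(
                    field, cfg, blinking=None, seed=seed + int(p),
                    channels=("confocal",), keep_line_stack=False,
                )
                images[p] = stack.channels["confocal"].astype(float)
            else:
                stack = simulate_acquisition(
                    field, cfg, sted_fwhm_nm=effective_sted_fwhm(250.0, p, 50.0),
                    blinking=None, seed=seed + int(p),
                    channels=("STED", "STEDonly"), keep_line_stack=False,
                )
                images[p] = compute_stedsub(
                    stack.channels["STED"], stack.channels["STEDonly"]
                )
        return images

    def test_curve_follows_resolution_law(self):
        from qdsted.imaging_model import effective_sted_fwhm

        powers = [0.0, 25.0, 75.0, 150.0, 300.0]
        # half-width 12 px = 300 nm so the window spans the confocal peak too
        curve = resolution_vs_power(
            self.sweep_images(powers), pixel_size_nm=25.0, roi_halfwidth_px=12
        )
        expected = effective_sted_fwhm(250.0, np.asarray(powers), 50.0)
        assert np.all(np.abs(curve.fwhm_nm - expected) / expected < 0.10)
        assert curve.n_per_point.min() >= 5

    def test_empty_power_point_flagged_not_dropped(self):
        images = self.sweep_images([0.0, 50.0])
        images[80.0] = np.zeros((201, 201))
        curve = resolution_vs_power(images, pixel_size_nm=25.0)
        assert curve.powers_mW.size == 3
        assert np.isnan(curve.fwhm_nm[list(curve.powers_mW).index(80.0)])
        assert any("80" in f for f in curve.flags)


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        g = [1.0, 2.0, 3.0, 4.0, 5.0]
        cmp = compare_groups(g, g)
        assert cmp.p_value >= 0.99
        assert cmp.stars == "ns"

    def test_blinking_ratio_means_give_40_percent_decrease(self):
        # group means 0.44 (Mowiol) vs 0.74 (PBS): relative decrease ~40%
        assert relative_change_pct(0.44, 0.74) == pytest.approx(-40.5, abs=0.1)

    def test_brightness_means_give_403_percent_ratio(self):
        # group means 826 vs 205 counts: ratio form ~403%
        assert ratio_pct(826.0, 205.0) == pytest.approx(403.0, abs=0.5)

    def test_clearly_separated_groups_get_four_stars(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.44, 0.05, 400)
        b = rng.normal(0.74, 0.05, 400)
        cmp = compare_groups(a, b)
        assert cmp.stars == "****"
        assert cmp.p_value < 1e-4

    def test_small_group_rejected(self):
        with pytest.raises(InputError):
            compare_groups([1.0], [1.0, 2.0])


class TestAnalyzeQd:
    def test_record_fields_populated(self):
        cfg = ScanConfig(30.0, (21, 21), 20.0, 10)
        c = cfg.fov_nm[0] / 2
        field = QDField(positions_nm=np.array([[c, c]]), photon_rate_per_us=2.0, multiplicity=1)
        stack = simulate_acquisition(
            field, cfg, blinking=None, seed=4, channels=("STED", "STEDonly")
        )
        sub = compute_stedsub(stack.channels["STED"], stack.channels["STEDonly"])
        rec = analyze_qd(sub, (10.0, 10.0), 30.0)
        assert rec.blinking_pixel_ratio == pytest.approx(0.0, abs=0.05)
        assert rec.integrated_brightness_counts > 0
        assert rec.fwhm_nm == pytest.approx(65.0, rel=0.2)
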