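"""Desk-scale reproduction experiments combining the package's stages.

Each function sets up one of the study conditions the package models —
telegraph blinking, subtraction-based halo removal, acquisition-schedule
comparisons, the depletion resolution law, donut-based cluster
classification with colocalization phantoms, and channel bleed-through —
runs the full measurement chain on synthetic data, and returns the
measured quantities. Problem sizes are chosen so every experiment runs in
seconds to a couple of minutes on a laptop; seeds make every run exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cluster_and_coloc import (
    bleedthrough_matrix,
    classify_multiplicity,
    compute_sfp,
    distances_to_tubulin,
    donut_central_ratio,
    fraction_within,
    qd_fraction_inside,
)
from .errors import UndefinedSFPError
from .imaging_model import ResolutionCurve, ScanConfig, effective_sted_fwhm, fit_resolution_curve
from .qd_photophysics import (
    analyze_qd,
    compare_groups,
    detect_qds,
    fit_line_profile,
)
from .sted_processing import compute_stedsub
from .synthetic_data import (
    BlinkingModel,
    QDField,
    generate_cell_scene,
    simulate_acquisition,
)

__all__ = [
    "telegraph_occupancy",
    "stedsub_fwhm_recovery",
    "schedule_comparison",
    "resolution_law_recovery",
    "classification_study",
    "coloc_phantom_study",
    "bleedthrough_study",
    "single_qd_roi_config",
]

#: pixels across one full scan line in the reference acquisitions (10 um at 30 nm)
FULL_LINE_PX = 333


def single_qd_roi_config(dwell_us: float, n_repeats: int, roi_px: int = 41,
                         pixel_size_nm: float = 30.0) -> ScanConfig:
    """Scan config for a single-QD region of interest cut from a full line.

    The flyback pads each line pass to the duration of a full
    ``FULL_LINE_PX``-pixel line, so the time between successive repeats of
    a line — which sets how strongly blinking decorrelates between
    repeats — matches a full-frame acquisition.
    """
    return ScanConfig(
        pixel_size_nm=pixel_size_nm,
        image_shape_px=(roi_px, roi_px),
        dwell_time_us=dwell_us,
        n_line_repeats=n_repeats,
        flyback_time_us=(FULL_LINE_PX - roi_px) * dwell_us,
    )


def telegraph_occupancy(seed: int, duration_ms: float = 1e4,
                        model: BlinkingModel | None = None) -> dict:
    """Long-run ON-time fraction of one blink trace vs renewal theory.

    The expected occupancy is ``tau_on / (tau_on + tau_off)`` and the
    asymptotic standard error of the time average over a window ``T`` is
    ``sqrt(2 tau_on^2 tau_off^2 / ((tau_on + tau_off)^3 T))``.
    """
    from .synthetic_data import simulate_blink_trace

    model = model or BlinkingModel()
    trace = simulate_blink_trace(model, duration_ms, seed=seed)
    tau_on, tau_off = model.tau_on_ms, model.tau_off_ms
    expected = tau_on / (tau_on + tau_off)
    se = np.sqrt(2 * tau_on**2 * tau_off**2 / ((tau_on + tau_off) ** 3 * duration_ms))
    return {
        "measured_on_fraction": trace.on_time_fraction(),
        "expected_on_fraction": expected,
        "standard_error": float(se),
        "n_segments": int(trace.states.size),
    }


def _simulate_single_qd(config: ScanConfig, seed: int, blinking: BlinkingModel | None,
                        photon_rate: float = 1.0):
    c = config.fov_nm[0] / 2
    field = QDField(positions_nm=np.array([[c, c]]), photon_rate_per_us=photon_rate,
                    multiplicity=1)
    stack = simulate_acquisition(
        field, config, blinking=blinking, dark_counts_per_us=0.0005, seed=seed,
        channels=("STED", "STEDonly"), keep_line_stack=False,
    )
    sub = compute_stedsub(stack.channels["STED"], stack.channels["STEDonly"])
    variance = stack.channels["STED"] + stack.channels["STEDonly"]
    return sub, variance


def stedsub_fwhm_recovery(seed: int, n_seeds: int = 50, sted_fwhm_nm: float = 65.0) -> dict:
    """Lorentzian FWHM of STEDsub single-QD profiles vs the configured width.

    Uses the optimized 10 x 20 us schedule with emitters held ON: the study
    isolates the subtraction + fitting chain, so the emitter is static and
    only shot noise perturbs the profile (blinking biases apparent widths,
    a separate effect measured by the schedule comparison). Also reports
    the residual halo in the donut-crest annulus relative to the
    pre-subtraction halo.
    """
    config = single_qd_roi_config(20.0, 10)
    px = config.pixel_size_nm
    rows, cols = config.image_shape_px
    ss = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    fwhms, halo_residual, halo_before = [], [], []
    rr, cc = np.mgrid[0:rows, 0:cols]
    r_px = np.hypot(rr - rows // 2, cc - cols // 2)
    annulus = (r_px >= 6) & (r_px <= 10)
    for s in ss:
        sub, variance = _simulate_single_qd(config, int(s), None)
        records = detect_qds(sub, min_distance_px=5, variance_image=variance)
        if not records:
            continue
        # profile through the brightest of the three central rows
        center_row = records[0].center_px[0]
        r0 = int(round(center_row))
        rows_cand = [r for r in (r0 - 1, r0, r0 + 1) if 0 <= r < rows]
        kernel = np.array([0.25, 0.5, 0.25])
        r_best = max(rows_cand, key=lambda r: np.convolve(sub[r], kernel, "same").max())
        x = (np.arange(cols) + 0.5) * px
        try:
            fit = fit_line_profile(x, sub[r_best], model="lorentzian", with_offset=True)
        except Exception:
            continue
        # a row at offset dy cuts the radial Lorentzian into a widened
        # Lorentzian of width w*sqrt(1 + 4 dy^2 / w^2); invert exactly
        dy = (r_best - center_row) * px
        w2 = fit.fwhm_nm**2 - 4.0 * dy**2
        if w2 <= (0.5 * px) ** 2:
            continue
        w = float(np.sqrt(w2))
        # fits broader than the diffraction limit are failed measurements
        if w > 250.0:
            continue
        fwhms.append(w)
        halo_residual.append(sub[annulus].mean())
        halo_before.append((variance[annulus] / 2).mean())
    return {
        "mean_fwhm_nm": float(np.mean(fwhms)),
        "sd_fwhm_nm": float(np.std(fwhms)),
        "configured_fwhm_nm": sted_fwhm_nm,
        "n_fits": len(fwhms),
        "halo_residual_fraction": float(np.mean(halo_residual) / np.mean(halo_before)),
    }


@dataclass
class ScheduleResult:
    label: str
    blink_ratios: np.ndarray
    brightness: np.ndarray
    n_detected: int
    n_simulated: int


def schedule_comparison(seed: int, n_per_schedule: int = 200) -> dict:
    """Blinking pixel ratio and brightness across dwell/repeat schedules.

    Simulates ``n_per_schedule`` QDs per schedule (1x200 us, 10x20 us,
    100x2 us — always 200 us per pixel), runs subtraction, detection and
    the blink-map measurement on each, and compares the per-QD
    distributions between schedules with the two-sided rank-sum test.

    Each QD is scanned in a compact 11-pixel region with no flyback, so a
    repeated line pass takes ~0.2 ms or less — shorter than the dark-state
    lifetime — and the repeats of a row tile the same total span
    (11 x 200 us) under every schedule. Splitting the dwell into more,
    faster passes then spreads each pixel's exposure over that span: the
    single-pass schedule probes one contiguous 200 us window per pixel
    (dark periods imprint directly), while both repeated schedules
    time-average over the identical ~2 ms span and are therefore
    statistically equivalent to each other.
    """
    schedules = [("1x200us", 200.0, 1), ("10x20us", 20.0, 10), ("100x2us", 2.0, 100)]
    ss = np.random.SeedSequence(seed).generate_state(3 * n_per_schedule) % (2**31)
    results: dict[str, ScheduleResult] = {}
    for i, (label, dwell, reps) in enumerate(schedules):
        config = ScanConfig(
            pixel_size_nm=30.0, image_shape_px=(11, 11), dwell_time_us=dwell,
            n_line_repeats=reps,
        )
        ratios, brights = [], []
        for j in range(n_per_schedule):
            s = int(ss[i * n_per_schedule + j])
            sub, variance = _simulate_single_qd(config, s, BlinkingModel())
            records = detect_qds(sub, min_distance_px=4, variance_image=variance)
            if not records:
                continue
            rec = analyze_qd(sub, records[0].center_px, config.pixel_size_nm)
            ratios.append(rec.blinking_pixel_ratio)
            brights.append(rec.integrated_brightness_counts)
        results[label] = ScheduleResult(
            label, np.asarray(ratios), np.asarray(brights), len(ratios), n_per_schedule
        )
    r = results
    ratio_1_vs_10 = compare_groups(r["1x200us"].blink_ratios, r["10x20us"].blink_ratios)
    ratio_10_vs_100 = compare_groups(r["10x20us"].blink_ratios, r["100x2us"].blink_ratios)
    bright_1_vs_10 = compare_groups(r["1x200us"].brightness, r["10x20us"].brightness)
    return {
        "blink_ratio_mean": {k: float(v.blink_ratios.mean()) for k, v in r.items()},
        "brightness_mean": {k: float(v.brightness.mean()) for k, v in r.items()},
        "n_detected": {k: v.n_detected for k, v in r.items()},
        "ratio_p_1x_vs_10x": ratio_1_vs_10.p_value,
        "ratio_p_10x_vs_100x": ratio_10_vs_100.p_value,
        "brightness_p_1x_vs_10x": bright_1_vs_10.p_value,
        "results": r,
    }


def resolution_law_recovery(
    seed: int,
    confocal_fwhm_nm: float = 250.0,
    saturation_power_mW: float = 12.0,
    noise_fraction: float = 0.05,
    n_qds_per_point: int = 10,
) -> dict:
    """Fit the resolution law to a noisy 8-point simulated power sweep.

    The synthetic curve mimics the measured resolution-improvement data:
    the confocal width saturates towards the super-resolved regime, with
    ~65 nm around 168 mW of depletion power. Each sweep point is the mean
    of ``n_qds_per_point`` per-QD widths carrying ``noise_fraction``
    multiplicative Gaussian scatter, matching how such curves are measured
    (one point = the average of several QDs).
    """
    rng = np.random.default_rng(seed)
    powers = np.array([0.0, 10.0, 25.0, 50.0, 85.0, 120.0, 168.0, 250.0])
    truth = effective_sted_fwhm(confocal_fwhm_nm, powers, saturation_power_mW)
    per_qd = truth[:, None] * (
        1.0 + noise_fraction * rng.standard_normal((powers.size, n_qds_per_point))
    )
    noisy = per_qd.mean(axis=1)
    d_c, p_sat, resid = fit_resolution_curve(
        ResolutionCurve(powers, noisy, fwhm_sd_nm=per_qd.std(axis=1))
    )
    return {
        "fitted_confocal_fwhm_nm": d_c,
        "fitted_saturation_power_mW": p_sat,
        "true_confocal_fwhm_nm": confocal_fwhm_nm,
        "true_saturation_power_mW": saturation_power_mW,
        "fwhm_at_168mW_nm": effective_sted_fwhm(d_c, 168.0, p_sat),
        "residual": resid,
        "n_points": int(powers.size),
    }


def classification_study(seed: int, n_per_class: int = 50) -> dict:
    """Single-vs-cluster classification accuracy from STEDonly donuts.

    Simulates isolated singles and 2-3-member clusters at study-like
    counts, computes the donut central ratio of each, classifies at the
    default cutoff and scores against the ground truth.
    """
    config = ScanConfig(30.0, (51, 51), 20.0, 10)
    c = config.fov_nm[0] / 2
    rng = np.random.default_rng(seed)
    ss = np.random.SeedSequence(seed + 1).generate_state(2 * n_per_class) % (2**31)

    def ratio_for(multiplicity, s):
        field = QDField(
            positions_nm=np.array([[c, c]]), photon_rate_per_us=1.0,
            multiplicity=multiplicity,
        )
        stack = simulate_acquisition(
            field, config, blinking=None, seed=int(s), channels=("STEDonly",),
            keep_line_stack=False,
        )
        return donut_central_ratio(
            stack.channels["STEDonly"].astype(float), (25, 25), ring_radii_px=(7.0, 10.0)
        )

    single_ok = sum(
        classify_multiplicity(ratio_for(1, ss[i])) == "single" for i in range(n_per_class)
    )
    cluster_ok = sum(
        classify_multiplicity(ratio_for(int(rng.integers(2, 4)), ss[n_per_class + i]))
        == "cluster"
        for i in range(n_per_class)
    )
    balanced = 0.5 * (single_ok / n_per_class + cluster_ok / n_per_class)
    return {
        "balanced_accuracy": balanced,
        "single_accuracy": single_ok / n_per_class,
        "cluster_accuracy": cluster_ok / n_per_class,
        "n_per_class": n_per_class,
    }


def coloc_phantom_study(
    seed: int,
    n_qds: int = 50,
    fraction_inside: float = 0.5,
    fraction_near: float = 0.68,
    n_scenes_sfp: int = 100,
) -> dict:
    """Colocalization metrics against constructed phantom ground truth.

    QDFI and the fraction of QDs within 200 nm of tubulin are compared
    with the constructed fractions (they must agree exactly by
    construction); nearest-tubulin distances are checked against an
    exhaustive all-pixel search. The SFP is additionally averaged over
    label-level phantoms with equal clustering inside and outside
    vesicles, where its expected value is 1.
    """
    config = ScanConfig(30.0, (334, 334), 20.0, 1)
    scene = generate_cell_scene(
        n_qds=n_qds, n_vesicles=n_qds // 2, vesicle_radius_nm=200.0,
        fraction_inside=fraction_inside, tubulin_density=5,
        fraction_near_tubulin=fraction_near, near_distance_nm=200.0,
        config=config, seed=seed, min_separation_nm=450.0,
    )
    px = config.pixel_size_nm
    centers = scene.field.positions_nm
    mask = scene.vesicle_masks["generic"]
    qdfi = qd_fraction_inside(centers, mask, px)
    dists = distances_to_tubulin(centers, scene.tubulin_mask, px)
    frac200 = fraction_within(dists, 200.0)

    # exhaustive oracle for the distances
    true_rc = np.argwhere(scene.tubulin_mask)
    true_xy = np.column_stack([true_rc[:, 1] + 0.5, true_rc[:, 0] + 0.5]) * px
    brute = np.empty(len(centers))
    for i, cpos in enumerate(centers):
        d = np.hypot(true_xy[:, 0] - cpos[0], true_xy[:, 1] - cpos[1]).min()
        r, col = int(cpos[1] // px), int(cpos[0] // px)
        brute[i] = 0.0 if scene.tubulin_mask[r, col] else d
    max_dist_err = float(np.max(np.abs(dists - brute)))

    rng = np.random.default_rng(seed + 2)
    sfps = []
    for _ in range(n_scenes_sfp):
        inside = ["cluster" if rng.random() < 0.3 else "single" for _ in range(25)]
        outside = ["cluster" if rng.random() < 0.3 else "single" for _ in range(25)]
        try:
            sfps.append(compute_sfp(inside, outside))
        except UndefinedSFPError:
            continue
    return {
        "qdfi": qdfi,
        "constructed_fraction_inside": fraction_inside,
        "fraction_within_200nm": frac200,
        "constructed_fraction_near": fraction_near,
        "max_distance_error_nm": max_dist_err,
        "mean_distance_nm": float(dists.mean()),
        "median_distance_nm": float(np.median(dists)),
        "sfp_equal_clustering_mean": float(np.mean(sfps)),
        "n_qds": n_qds,
    }


def bleedthrough_study(seed: int, injected_ratio: float = 0.10) -> dict:
    """Recover an injected cross-channel signal ratio from noisy images.

    One fluorophore is imaged alone in its own channel and in a second
    channel carrying ``injected_ratio`` of its structure signal over a
    shared diffuse background; the bleed-through matrix must recover the
    injected ratio.
    """
    rng = np.random.default_rng(seed)
    mask = np.zeros((120, 120), dtype=bool)
    mask[30:80, 25:95] = True
    own_expect = np.where(mask, 180.0, 4.0)
    cross_expect = 4.0 + injected_ratio * (own_expect - 4.0)
    images = {
        "QD740": {
            "QD740": rng.poisson(own_expect).astype(float),
            "dye": rng.poisson(cross_expect).astype(float),
        }
    }
    matrix = bleedthrough_matrix(images, {"QD740": mask})
    return {
        "recovered_ratio": float(matrix.loc["QD740", "dye"]),
        "injected_ratio": injected_ratio,
        "n_structure_px": int(mask.sum()),
    }
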