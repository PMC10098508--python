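"""Per-quantum-dot photophysics: detection, blinking, brightness, FWHM.

A blinking quantum dot scanned line by line leaves dark pixel runs along
the fast axis wherever it dwelt in the OFF state. The *blinking map*
classifies each pixel of a QD's footprint as ON or OFF by comparing the
recorded counts with the counts predicted by the QD's fitted radial
profile at full (non-blinking) amplitude; the *blinking pixel ratio* is
the OFF fraction of the footprint (0 = never dark, 1 = always dark).
*Integrated brightness* is the background-subtracted count sum over the
footprint. Resolution is measured as the FWHM of a Lorentzian (depleted)
or Gaussian (confocal) fit to a one-pixel-wide line profile along the
fast axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import ranksums
from skimage.feature import peak_local_max

from .errors import (
    DegenerateInputError,
    FitError,
    InputError,
    InsufficientDataError,
    ParameterError,
)
from .imaging_model import ResolutionCurve

__all__ = [
    "QDRecord",
    "BlinkMap",
    "LineProfileFit",
    "GroupComparison",
    "detect_qds",
    "extract_roi",
    "predict_qd_image",
    "compute_blink_map",
    "blink_map_for_qd",
    "blinking_pixel_ratio",
    "integrated_brightness",
    "fit_line_profile",
    "fit_double_lorentzian",
    "resolution_vs_power",
    "compare_groups",
    "relative_change_pct",
    "ratio_pct",
    "analyze_qd",
]

_LN2_4 = 4.0 * np.log(2.0)


@dataclass
class QDRecord:
    """Measurements for one detected quantum dot."""

    center_px: tuple[float, float]  # (row, col)
    center_nm: tuple[float, float] | None = None  # (x, y)
    roi_halfwidth_px: int | None = None
    peak_counts: float | None = None
    integrated_brightness_counts: float | None = None
    blinking_pixel_ratio: float | None = None
    fwhm_nm: float | None = None
    fit_model: str | None = None
    donut_central_ratio: float | None = None
    multiplicity_class: str = "unclassified"


@dataclass
class BlinkMap:
    """ON/OFF pixel classification over a QD's footprint.

    ``considered_mask`` marks pixels where the classification is defined
    (predicted signal above the footprint floor); ``on_mask`` is a subset.
    """

    roi_counts: np.ndarray
    on_mask: np.ndarray
    considered_mask: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.on_mask & ~self.considered_mask):
            raise InputError("on_mask must be a subset of considered_mask")


@dataclass
class LineProfileFit:
    fwhm_nm: float
    amplitude: float
    center_nm: float
    offset: float
    residual: float
    model: str = "lorentzian"


@dataclass
class GroupComparison:
    """Two-sided rank-sum comparison of two measurement groups.

    ``effect_pct`` is the relative difference of means
    ``100 (mean_a - mean_b) / mean_b``; ``ratio_pct`` is the ratio form
    ``100 mean_a / mean_b``.
    """

    p_value: float
    stars: str
    effect_pct: float
    ratio_pct: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def detect_qds(
    image: np.ndarray,
    min_distance_px: int = 3,
    threshold_sigma: float = 6.0,
    pixel_size_nm: float | None = None,
    smooth_sigma_px: float = 1.0,
    variance_image: np.ndarray | None = None,
    local_noise_window_px: int | None = None,
) -> list[QDRecord]:
    """Detect isolated emitters as local maxima above a noise threshold.

    The image is lightly Gaussian-smoothed (matched-filter style: shot
    noise is single-pixel while emitters span several pixels) and peaks
    must exceed the median by ``threshold_sigma`` noise standard
    deviations. Shot noise grows with the local signal, so when a
    per-pixel ``variance_image`` is supplied (for a subtraction image
    ``STED - STEDonly`` it is ``STED + STEDonly``; for a raw count image,
    the image itself) the threshold follows the local Poisson scale;
    otherwise a global scaled-median-absolute-deviation estimate is used.
    Non-maximum suppression within ``min_distance_px``; centers are
    refined to subpixel precision by center of mass in a 3x3
    neighbourhood. An empty list is a valid result.

    ``local_noise_window_px`` additionally floors the noise map at a
    running local scaled-MAD estimate. Blinking inflates fluctuations
    beyond the Poisson level (the two subtraction channels blink
    independently), which only an empirical local estimate captures; the
    window should be several times the emitter footprint so the emitter
    itself does not dominate its own noise estimate.
    """
    from scipy.ndimage import gaussian_filter, median_filter

    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise InputError("image is empty")
    smoothed = gaussian_filter(img, smooth_sigma_px) if smooth_sigma_px > 0 else img
    med = float(np.median(smoothed))
    global_sigma = max(1.4826 * float(np.median(np.abs(smoothed - med))), 0.25)
    if variance_image is None:
        sigma_map = np.full_like(smoothed, global_sigma)
    else:
        var = np.asarray(variance_image, dtype=float)
        if var.shape != img.shape:
            raise InputError("variance_image shape must match image shape")
        # white-noise variance shrinks by 1/(4 pi s^2) under Gaussian smoothing
        gain = 1.0 / (4.0 * np.pi * smooth_sigma_px**2) if smooth_sigma_px > 0 else 1.0
        sigma_map = np.sqrt(np.clip(gaussian_filter(var, smooth_sigma_px), 1.0, None) * gain)
    if local_noise_window_px:
        win = int(local_noise_window_px) | 1
        resid = smoothed - median_filter(smoothed, size=win)
        local_mad = 1.4826 * median_filter(np.abs(resid), size=win)
        sigma_map = np.maximum(sigma_map, local_mad)
    candidates = peak_local_max(
        smoothed, min_distance=int(min_distance_px), threshold_abs=float(med),
        exclude_border=False,
    )
    records: list[QDRecord] = []
    for r, c in candidates:
        if smoothed[r, c] - med < threshold_sigma * sigma_map[r, c]:
            continue
        r0, r1 = max(r - 1, 0), min(r + 2, img.shape[0])
        c0, c1 = max(c - 1, 0), min(c + 2, img.shape[1])
        w = np.clip(img[r0:r1, c0:c1] - med, 0, None)
        if w.sum() > 0:
            rr, cc = np.mgrid[r0:r1, c0:c1]
            rcom = float((w * rr).sum() / w.sum())
            ccom = float((w * cc).sum() / w.sum())
        else:  # pragma: no cover - peak above threshold has positive mass
            rcom, ccom = float(r), float(c)
        center_nm = None
        if pixel_size_nm is not None:
            center_nm = ((ccom + 0.5) * pixel_size_nm, (rcom + 0.5) * pixel_size_nm)
        records.append(
            QDRecord(center_px=(rcom, ccom), center_nm=center_nm, peak_counts=float(img[r, c]))
        )
    records.sort(key=lambda rec: -(rec.peak_counts or 0.0))
    return records


def extract_roi(
    image: np.ndarray, center_px: tuple[float, float], halfwidth_px: int
) -> tuple[np.ndarray, tuple[int, int]]:
    """Cut a ``(2h+1)``-square ROI around a center, clipped at the borders.

    Returns the ROI and its ``(row, col)`` origin in the full image.
    """
    r, c = int(round(center_px[0])), int(round(center_px[1]))
    r0, r1 = max(r - halfwidth_px, 0), min(r + halfwidth_px + 1, image.shape[0])
    c0, c1 = max(c - halfwidth_px, 0), min(c + halfwidth_px + 1, image.shape[1])
    return np.asarray(image)[r0:r1, c0:c1], (r0, c0)


def _radial_model(model: str, r_nm: np.ndarray, fwhm_nm: float) -> np.ndarray:
    if model == "gaussian":
        return np.exp(-_LN2_4 * r_nm**2 / fwhm_nm**2)
    return 1.0 / (1.0 + 4.0 * r_nm**2 / fwhm_nm**2)


def predict_qd_image(
    roi: np.ndarray,
    center_px: tuple[float, float],
    pixel_size_nm: float,
    model: str = "lorentzian",
) -> np.ndarray:
    """Predict the full-ON (non-blinking) image of a QD inside its ROI.

    The width comes from a 1D fit to the radially averaged profile (robust
    to dark blink runs, which scale the radial mean but not its shape);
    the amplitude comes from the brightest ON rows: within rows whose
    radial factor exceeds 0.5 the lightly smoothed row maximum divided by
    that factor estimates the full-ON peak, and the maximum over such rows
    is taken since the brightest rows were scanned while the QD was ON.
    """
    roi = np.asarray(roi, dtype=float)
    if roi.max() <= 0:
        raise DegenerateInputError("ROI contains no positive counts")
    cr, cc = center_px
    rr, cci = np.mgrid[0 : roi.shape[0], 0 : roi.shape[1]]
    r_nm = np.hypot(rr - cr, cci - cc) * pixel_size_nm

    # radially averaged profile, mirrored so the fit sees a full peak
    bins = np.round(r_nm / pixel_size_nm).astype(int)
    n_bins = bins.max() + 1
    sums = np.bincount(bins.ravel(), weights=roi.ravel(), minlength=n_bins)
    cnts = np.bincount(bins.ravel(), minlength=n_bins)
    prof = sums / np.maximum(cnts, 1)
    radii = np.arange(n_bins) * pixel_size_nm
    x = np.concatenate([-radii[:0:-1], radii])
    y = np.concatenate([prof[:0:-1], prof])
    try:
        width_nm = fit_line_profile(x, y, model=model, with_offset=True).fwhm_nm
    except FitError:
        # heavy blinking can leave a radial profile too distorted for a
        # least-squares fit; fall back to the crude half-maximum width
        width_nm = _estimate_width(x, y, float(np.median(prof[-3:])))
    # a width below one pixel is unmeasurable on this grid; clamping keeps
    # the row-factor window non-empty even for collapsed fits
    width_nm = max(width_nm, pixel_size_nm)

    row_r_nm = np.abs(np.arange(roi.shape[0]) - cr) * pixel_size_nm
    row_factor = _radial_model(model, row_r_nm, width_nm)
    kernel = np.array([0.25, 0.5, 0.25])
    amp = 0.0
    for i in np.nonzero(row_factor >= 0.5)[0]:
        smooth = np.convolve(roi[i], kernel, mode="same")
        amp = max(amp, float(smooth.max()) / row_factor[i])
    if amp <= 0:
        raise DegenerateInputError("could not estimate a positive full-ON amplitude")
    return amp * _radial_model(model, r_nm, width_nm)


def compute_blink_map(
    roi: np.ndarray,
    model_prediction: np.ndarray,
    off_fraction_cutoff: float = 0.25,
    considered_floor: float = 0.20,
) -> BlinkMap:
    """Classify footprint pixels ON/OFF against a full-ON prediction.

    Pixels where the prediction exceeds ``considered_floor`` of its peak
    form the footprint; a footprint pixel is ON when its counts reach
    ``off_fraction_cutoff`` of the locally predicted full-ON counts.
    """
    roi = np.asarray(roi, dtype=float)
    pred = np.asarray(model_prediction, dtype=float)
    if roi.shape != pred.shape:
        raise InputError(f"shape mismatch: roi {roi.shape} vs prediction {pred.shape}")
    peak = pred.max()
    if peak <= 0:
        raise DegenerateInputError("model prediction is non-positive everywhere")
    considered = pred >= considered_floor * peak
    on = considered & (roi >= off_fraction_cutoff * pred)
    return BlinkMap(roi_counts=roi, on_mask=on, considered_mask=considered)


def blink_map_for_qd(
    roi: np.ndarray,
    center_px: tuple[float, float],
    pixel_size_nm: float,
    model: str = "lorentzian",
    off_fraction_cutoff: float = 0.25,
    considered_floor: float = 0.20,
) -> BlinkMap:
    """Build the blink map of one QD from its ROI alone."""
    pred = predict_qd_image(roi, center_px, pixel_size_nm, model=model)
    return compute_blink_map(roi, pred, off_fraction_cutoff, considered_floor)


def blinking_pixel_ratio(blink_map: BlinkMap) -> float:
    """OFF fraction of the considered footprint."""
    n_cons = int(blink_map.considered_mask.sum())
    if n_cons == 0:
        raise DegenerateInputError("considered mask is empty")
    n_off = int((blink_map.considered_mask & ~blink_map.on_mask).sum())
    return n_off / n_cons


def integrated_brightness(
    roi: np.ndarray,
    blink_map: BlinkMap,
    background_per_px: float = 0.0,
    pixels: str = "considered",
) -> float:
    """Background-subtracted count sum over the footprint.

    ``pixels`` selects the summation region: ``"considered"`` (default,
    whole footprint) or ``"on"`` (ON pixels only). Per-pixel values are
    floored at zero after background subtraction.
    """
    roi = np.asarray(roi, dtype=float)
    if roi.shape != blink_map.considered_mask.shape:
        raise InputError("roi and blink map shapes differ")
    if pixels not in ("considered", "on"):
        raise ParameterError(f"pixels must be 'considered' or 'on', got {pixels!r}")
    mask = blink_map.considered_mask if pixels == "considered" else blink_map.on_mask
    return float(np.clip(roi[mask] - background_per_px, 0, None).sum())


def _profile_fn(model: str):
    if model == "gaussian":
        return lambda x, A, c, w, b: A * np.exp(-_LN2_4 * (x - c) ** 2 / w**2) + b
    if model == "lorentzian":
        return lambda x, A, c, w, b: A / (1.0 + 4.0 * (x - c) ** 2 / w**2) + b
    raise ParameterError(f"unknown profile model {model!r}")


def _estimate_width(x: np.ndarray, y: np.ndarray, off: float) -> float:
    half = off + (y.max() - off) / 2.0
    above = y > half
    if above.sum() >= 2:
        xs = x[above]
        w = float(xs.max() - xs.min())
        if w > 0:
            return w
    return float((x.max() - x.min()) / 4.0)


def fit_line_profile(
    positions_nm: np.ndarray,
    counts: np.ndarray,
    model: str = "lorentzian",
    with_offset: bool = False,
) -> LineProfileFit:
    """Nonlinear least-squares fit of a 1D Lorentzian or Gaussian peak.

    Lorentzian: ``A / (1 + 4 (x-c)^2 / w^2) + b``;
    Gaussian: ``A exp(-4 ln2 (x-c)^2 / w^2) + b``; ``w`` is the FWHM (nm).
    The offset ``b`` is fixed at 0 unless ``with_offset``. Raises
    :class:`InsufficientDataError` for fewer than 5 samples and
    :class:`FitError` on non-convergence or a width pinned at its bounds.
    """
    x = np.asarray(positions_nm, dtype=float)
    y = np.asarray(counts, dtype=float)
    if x.shape != y.shape:
        raise InputError("positions and counts must have the same length")
    if x.size < 5:
        raise InsufficientDataError(f"need >= 5 samples spanning the peak, got {x.size}")
    fn = _profile_fn(model)
    span = float(x.max() - x.min())
    off0 = float(y.min()) if with_offset else 0.0
    a0 = max(float(y.max()) - off0, 1e-12)
    c0 = float(x[int(np.argmax(y))])
    w0 = _estimate_width(x, y, off0)
    w_lo, w_hi = span * 1e-4, span * 10.0
    if with_offset:
        p0 = (a0, c0, w0, off0)
        lb = [0.0, x.min() - span, w_lo, -np.inf]
        ub = [np.inf, x.max() + span, w_hi, np.inf]
        model_fn = fn
    else:
        p0 = (a0, c0, w0)
        lb, ub = [0.0, x.min() - span, w_lo], [np.inf, x.max() + span, w_hi]
        model_fn = lambda xx, A, c, w: fn(xx, A, c, w, 0.0)  # noqa: E731
    try:
        popt, _ = curve_fit(model_fn, x, y, p0=p0, bounds=(lb, ub), maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"{model} line-profile fit failed: {exc}") from exc
    w = float(popt[2])
    if w <= w_lo * 1.01 or w >= w_hi * 0.99:
        raise FitError(f"fitted FWHM {w:.3g} nm pinned at the bounds [{w_lo:.3g}, {w_hi:.3g}]")
    b = float(popt[3]) if with_offset else 0.0
    resid = float(np.linalg.norm(y - model_fn(x, *popt)))
    return LineProfileFit(
        fwhm_nm=w,
        amplitude=float(popt[0]),
        center_nm=float(popt[1]),
        offset=b,
        residual=resid,
        model=model,
    )


def fit_double_lorentzian(
    positions_nm: np.ndarray, counts: np.ndarray, with_offset: bool = False
) -> tuple[LineProfileFit, LineProfileFit]:
    """Fit a sum of two Lorentzian peaks; returns the two components.

    Used for line profiles crossing two nearby structures (for example a
    quantum dot sitting on a vesicle membrane).
    """
    x = np.asarray(positions_nm, dtype=float)
    y = np.asarray(counts, dtype=float)
    if x.size < 9:
        raise InsufficientDataError("need >= 9 samples for a double-peak fit")
    span = float(x.max() - x.min())
    off0 = float(y.min()) if with_offset else 0.0
    a0 = max(float(y.max()) - off0, 1e-12)
    c1 = float(x[int(np.argmax(y))])
    # second init center: maximum outside a guard zone around the first
    far = np.abs(x - c1) > span / 6
    c2 = float(x[far][int(np.argmax(y[far]))]) if far.any() else c1 + span / 4
    w0 = max(_estimate_width(x, y, off0) / 2, span * 1e-3)

    def fn(xx, A1, cc1, w1, A2, cc2, w2, b):
        return (
            A1 / (1 + 4 * (xx - cc1) ** 2 / w1**2)
            + A2 / (1 + 4 * (xx - cc2) ** 2 / w2**2)
            + b
        )

    w_lo, w_hi = span * 1e-4, span * 10
    p0 = [a0, c1, w0, a0 / 2, c2, w0] + ([off0] if with_offset else [])
    if with_offset:
        lb = [0, x.min() - span, w_lo, 0, x.min() - span, w_lo, -np.inf]
        ub = [np.inf, x.max() + span, w_hi, np.inf, x.max() + span, w_hi, np.inf]
        model_fn = fn
    else:
        lb = [0, x.min() - span, w_lo, 0, x.min() - span, w_lo]
        ub = [np.inf, x.max() + span, w_hi, np.inf, x.max() + span, w_hi]
        model_fn = lambda xx, A1, cc1, w1, A2, cc2, w2: fn(xx, A1, cc1, w1, A2, cc2, w2, 0.0)  # noqa: E731
    try:
        popt, _ = curve_fit(model_fn, x, y, p0=p0, bounds=(lb, ub), maxfev=40000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"double Lorentzian fit failed: {exc}") from exc
    b = float(popt[6]) if with_offset else 0.0
    resid = float(np.linalg.norm(y - model_fn(x, *popt)))
    comps = [
        LineProfileFit(float(popt[i + 2]), float(popt[i]), float(popt[i + 1]), b, resid)
        for i in (0, 3)
    ]
    comps.sort(key=lambda f: f.center_nm)
    return comps[0], comps[1]


def resolution_vs_power(
    images: dict[float, np.ndarray],
    pixel_size_nm: float,
    n_qds_per_point: int = 10,
    roi_halfwidth_px: int = 5,
    min_distance_px: int = 3,
    threshold_sigma: float = 5.0,
) -> ResolutionCurve:
    """Measure a FWHM-versus-depletion-power curve from one image per power.

    Per power: detect emitters, fit a one-pixel-wide fast-axis line profile
    through each (Gaussian at zero power, Lorentzian when depleted), keep
    the ``n_qds_per_point`` brightest successful fits, and report their
    mean and standard deviation. Points backed by fewer fits than requested
    are kept and flagged rather than dropped.
    """
    if not images:
        raise InsufficientDataError("need at least one power")
    powers = sorted(images)
    means, sds, ns, flags = [], [], [], []
    for p in powers:
        model = "gaussian" if p == 0 else "lorentzian"
        records = detect_qds(
            images[p], min_distance_px=min_distance_px, threshold_sigma=threshold_sigma
        )
        fwhms = []
        for rec in records:
            roi, (r0, c0) = extract_roi(images[p], rec.center_px, roi_halfwidth_px)
            row = int(round(rec.center_px[0])) - r0
            cols = np.arange(roi.shape[1])
            x = (cols + c0 + 0.5) * pixel_size_nm
            try:
                fit = fit_line_profile(x, roi[row], model=model, with_offset=True)
            except (FitError, InsufficientDataError):
                continue
            fwhms.append(fit.fwhm_nm)
            if len(fwhms) == n_qds_per_point:
                break
        if not fwhms:
            flags.append(f"power {p} mW: no successful fits")
            means.append(np.nan)
            sds.append(np.nan)
            ns.append(0)
            continue
        if len(fwhms) < n_qds_per_point:
            msg = f"power {p} mW: only {len(fwhms)}/{n_qds_per_point} successful fits"
            flags.append(msg)
            warnings.warn(msg, stacklevel=2)
        means.append(float(np.mean(fwhms)))
        sds.append(float(np.std(fwhms)))
        ns.append(len(fwhms))
    return ResolutionCurve(
        powers_mW=np.asarray(powers, dtype=float),
        fwhm_nm=np.asarray(means),
        fwhm_sd_nm=np.asarray(sds),
        n_per_point=np.asarray(ns),
        flags=flags,
    )


def relative_change_pct(mean_a: float, mean_b: float) -> float:
    """Relative difference of means, ``100 (mean_a - mean_b) / mean_b``."""
    if mean_b == 0:
        raise DegenerateInputError("reference mean is zero")
    return 100.0 * (mean_a - mean_b) / mean_b


def ratio_pct(mean_a: float, mean_b: float) -> float:
    """Ratio of means in percent, ``100 mean_a / mean_b``."""
    if mean_b == 0:
        raise DegenerateInputError("reference mean is zero")
    return 100.0 * mean_a / mean_b


_STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def compare_groups(a, b) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum comparison of two measurement groups.

    Chosen over a t-test because blinking-ratio and brightness
    distributions are strongly skewed. Stars follow the usual four-level
    convention (0.05, 0.01, 0.001, 0.0001).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs at least 2 values")
    stat = ranksums(a, b)
    p = float(stat.pvalue)
    stars = "ns"
    for level, code in _STAR_LEVELS:
        if p < level:
            stars = code
            break
    return GroupComparison(
        p_value=p,
        stars=stars,
        effect_pct=relative_change_pct(a.mean(), b.mean()),
        ratio_pct=ratio_pct(a.mean(), b.mean()),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=int(a.size),
        n_b=int(b.size),
    )


def analyze_qd(
    image: np.ndarray,
    center_px: tuple[float, float],
    pixel_size_nm: float,
    roi_halfwidth_px: int = 5,
    model: str = "lorentzian",
    background_per_px: float = 0.0,
    off_fraction_cutoff: float = 0.25,
    considered_floor: float = 0.20,
    brightness_pixels: str = "considered",
) -> QDRecord:
    """Measure one QD: blink map, blinking ratio, brightness, fast-axis FWHM.

    The FWHM comes from a one-pixel-wide line profile along the fast axis
    through the center; it is left absent when that fit fails (for example
    when the central line was scanned during a dark period).
    """
    roi, (r0, c0) = extract_roi(image, center_px, roi_halfwidth_px)
    center_roi = (center_px[0] - r0, center_px[1] - c0)
    bmap = blink_map_for_qd(
        roi, center_roi, pixel_size_nm, model=model,
        off_fraction_cutoff=off_fraction_cutoff, considered_floor=considered_floor,
    )
    ratio = blinking_pixel_ratio(bmap)
    brightness = integrated_brightness(
        roi, bmap, background_per_px=background_per_px, pixels=brightness_pixels
    )
    fwhm = None
    row = int(round(center_roi[0]))
    if 0 <= row < roi.shape[0]:
        x = (np.arange(roi.shape[1]) + c0 + 0.5) * pixel_size_nm
        try:
            fwhm = fit_line_profile(x, roi[row], model=model, with_offset=True).fwhm_nm
        except (FitError, InsufficientDataError):
            fwhm = None
    return QDRecord(
        center_px=center_px,
        center_nm=((center_px[1] + 0.5) * pixel_size_nm, (center_px[0] + 0.5) * pixel_size_nm),
        roi_halfwidth_px=roi_halfwidth_px,
        peak_counts=float(np.max(roi)),
        integrated_brightness_counts=brightness,
        blinking_pixel_ratio=ratio,
        fwhm_nm=fwhm,
        fit_model=model,
    )
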