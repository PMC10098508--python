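"""Analytic point-spread-function models and scan-time bookkeeping.

This module holds the pieces shared by the acquisition simulator and the
analysis code: the raster-scan geometry (:class:`ScanConfig`), analytic
focal intensity profiles (:class:`PSFModel`, :func:`render_psf`), the
depletion-power resolution law (:func:`effective_sted_fwhm`,
:func:`fit_resolution_curve`) and the per-pixel dwell clock
(:func:`pixel_clock`).

Conventions, used everywhere in the package:

* images are indexed ``[row, col]`` with 0-based indices;
* the fast scan axis is the column axis (lines run along x);
* pixel ``(i, j)`` covers ``[j*p, (j+1)*p) x [i*p, (i+1)*p)`` nm and its
  center sits at ``((j+0.5)*p, (i+0.5)*p)`` with ``p`` the pixel size;
* lengths are nm, times are microseconds (traces use ms), powers are mW.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, InsufficientDataError, ParameterError

__all__ = [
    "ScanConfig",
    "PSFModel",
    "ResolutionCurve",
    "render_psf",
    "effective_sted_fwhm",
    "fit_resolution_curve",
    "pixel_clock",
    "total_scan_duration_us",
]

_LN2_4 = 4.0 * np.log(2.0)


@dataclass(frozen=True)
class ScanConfig:
    """Raster-scan geometry and dwell/repeat schedule.

    Parameters
    ----------
    pixel_size_nm:
        Side of the square pixel, nm.
    image_shape_px:
        ``(rows, cols)`` of the raster.
    dwell_time_us:
        Time spent on a pixel during a single line pass, microseconds.
    n_line_repeats:
        Number of times each line is scanned before moving to the next
        row; the repeats of one pixel are summed in the final image.
    flyback_time_us:
        Dead time appended after each line pass (default 0). Setting it to
        ``(L - cols) * dwell_time_us`` emulates a small region of interest
        cut out of a full ``L``-pixel-wide scan line, which matters when
        blinking correlates with the inter-repeat gap.
    """

    pixel_size_nm: float
    image_shape_px: tuple[int, int]
    dwell_time_us: float
    n_line_repeats: int = 1
    flyback_time_us: float = 0.0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ParameterError(f"pixel_size_nm must be > 0, got {self.pixel_size_nm}")
        if self.dwell_time_us <= 0:
            raise ParameterError(f"dwell_time_us must be > 0, got {self.dwell_time_us}")
        if int(self.n_line_repeats) < 1:
            raise ParameterError(f"n_line_repeats must be >= 1, got {self.n_line_repeats}")
        if self.flyback_time_us < 0:
            raise ParameterError("flyback_time_us must be >= 0")
        rows, cols = self.image_shape_px
        if rows < 1 or cols < 1:
            raise ParameterError(f"image_shape_px must be positive, got {self.image_shape_px}")
        object.__setattr__(self, "image_shape_px", (int(rows), int(cols)))
        object.__setattr__(self, "n_line_repeats", int(self.n_line_repeats))

    @property
    def total_dwell_per_pixel_us(self) -> float:
        """Total time spent on each pixel over all line repeats."""
        return self.dwell_time_us * self.n_line_repeats

    @property
    def line_time_us(self) -> float:
        """Duration of one line pass including flyback."""
        return self.image_shape_px[1] * self.dwell_time_us + self.flyback_time_us

    def pixel_centers_nm(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(x_centers, y_centers)`` in nm; x along columns."""
        rows, cols = self.image_shape_px
        x = (np.arange(cols) + 0.5) * self.pixel_size_nm
        y = (np.arange(rows) + 0.5) * self.pixel_size_nm
        return x, y

    @property
    def fov_nm(self) -> tuple[float, float]:
        """Field of view ``(width_x, height_y)`` in nm."""
        rows, cols = self.image_shape_px
        return cols * self.pixel_size_nm, rows * self.pixel_size_nm


@dataclass(frozen=True)
class PSFModel:
    """Analytic focal intensity profile, peak-normalised to 1.

    ``kind`` is one of ``gaussian``, ``lorentzian`` (both parameterised by
    ``fwhm_nm``) or ``donut`` (parameterised by ``donut_scale_nm``, the
    radius of the intensity crest; the profile is exactly 0 at the center).
    """

    kind: str
    fwhm_nm: float | None = None
    donut_scale_nm: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "lorentzian", "donut"):
            raise ParameterError(f"unknown PSF kind {self.kind!r}")
        if self.kind in ("gaussian", "lorentzian"):
            if self.fwhm_nm is None or self.fwhm_nm <= 0:
                raise ParameterError(f"{self.kind} PSF requires fwhm_nm > 0, got {self.fwhm_nm}")
        else:
            if self.donut_scale_nm is None or self.donut_scale_nm <= 0:
                raise ParameterError(
                    f"donut PSF requires donut_scale_nm > 0, got {self.donut_scale_nm}"
                )

    def evaluate_r2(self, r2_nm2: np.ndarray | float) -> np.ndarray | float:
        """Evaluate the profile on squared radial distances (nm^2)."""
        r2 = np.asarray(r2_nm2, dtype=float)
        if self.kind == "gaussian":
            return np.exp(-_LN2_4 * r2 / self.fwhm_nm**2)
        if self.kind == "lorentzian":
            return 1.0 / (1.0 + 4.0 * r2 / self.fwhm_nm**2)
        u = r2 / self.donut_scale_nm**2
        return u * np.exp(1.0 - u)


@dataclass
class ResolutionCurve:
    """Measured FWHM versus depletion power.

    ``n_per_point`` records how many QDs were averaged at each power; a
    point backed by fewer fits than requested is kept and flagged by the
    producer rather than silently dropped.
    """

    powers_mW: np.ndarray
    fwhm_nm: np.ndarray
    fwhm_sd_nm: np.ndarray | None = None
    n_per_point: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.powers_mW = np.asarray(self.powers_mW, dtype=float)
        self.fwhm_nm = np.asarray(self.fwhm_nm, dtype=float)
        if self.powers_mW.shape != self.fwhm_nm.shape:
            raise ParameterError("powers_mW and fwhm_nm must have the same length")
        if np.any(np.diff(self.powers_mW) <= 0):
            raise ParameterError("powers_mW must be strictly increasing")
        for name in ("fwhm_sd_nm", "n_per_point"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if v.shape != self.powers_mW.shape:
                    raise ParameterError(f"{name} must match powers_mW in length")
                setattr(self, name, v)


def render_psf(
    model: PSFModel, config: ScanConfig, center_nm: tuple[float, float]
) -> np.ndarray:
    """Render an analytic PSF onto the pixel grid of ``config``.

    The pixel value is the profile evaluated at the pixel center (no
    integration over the pixel area). ``center_nm`` is ``(x, y)``.
    """
    x, y = config.pixel_centers_nm()
    cx, cy = center_nm
    r2 = (x[None, :] - cx) ** 2 + (y[:, None] - cy) ** 2
    return np.asarray(model.evaluate_r2(r2), dtype=float)


def effective_sted_fwhm(
    confocal_fwhm_nm: float, power_mW: float | np.ndarray, saturation_power_mW: float
) -> float | np.ndarray:
    """Resolution law ``d(I) = d_c / sqrt(1 + I/I_sat)``.

    ``d_c`` is the confocal (zero-depletion) FWHM and ``I_sat`` the
    saturation power of the depletion transition. Standard inverse-
    square-root STED scaling; reduces to ``d_c`` at zero power.
    """
    if confocal_fwhm_nm <= 0:
        raise ParameterError("confocal_fwhm_nm must be > 0")
    if saturation_power_mW <= 0:
        raise ParameterError("saturation_power_mW must be > 0")
    power = np.asarray(power_mW, dtype=float)
    if np.any(power < 0):
        raise ParameterError("power_mW must be >= 0")
    out = confocal_fwhm_nm / np.sqrt(1.0 + power / saturation_power_mW)
    return float(out) if np.ndim(power_mW) == 0 else out


def fit_resolution_curve(curve: ResolutionCurve) -> tuple[float, float, float]:
    """Least-squares fit of the resolution law to a measured curve.

    Returns ``(confocal_fwhm_nm, saturation_power_mW, residual_norm)``.
    Raises :class:`InsufficientDataError` for fewer than 3 powers and
    :class:`FitError` on non-convergence.
    """
    p = curve.powers_mW
    f = curve.fwhm_nm
    if p.size < 3:
        raise InsufficientDataError(f"need >= 3 powers to fit the resolution law, got {p.size}")

    def law(power, d_c, p_sat):
        return d_c / np.sqrt(1.0 + power / p_sat)

    d0 = float(np.max(f))
    p0 = float(np.median(p[p > 0])) if np.any(p > 0) else 1.0
    try:
        popt, _ = curve_fit(
            law, p, f, p0=(d0, p0), bounds=([1e-6, 1e-6], [np.inf, np.inf]), maxfev=20000
        )
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - scipy message passthrough
        raise FitError(f"resolution-law fit failed: {exc}") from exc
    residual = float(np.linalg.norm(f - law(p, *popt)))
    return float(popt[0]), float(popt[1]), residual


def pixel_clock(config: ScanConfig) -> np.ndarray:
    """Absolute dwell start time of every pixel visit, microseconds.

    Returns an array of shape ``(rows, n_line_repeats, cols)``. Scanning is
    line-by-line with repeats: all repeats of a row complete (each followed
    by flyback) before the next row starts; within a line pass, pixels are
    visited in column order.
    """
    rows, cols = config.image_shape_px
    reps = config.n_line_repeats
    line = config.line_time_us
    row_idx = np.arange(rows)[:, None, None]
    rep_idx = np.arange(reps)[None, :, None]
    col_idx = np.arange(cols)[None, None, :]
    return (row_idx * reps + rep_idx) * line + col_idx * config.dwell_time_us


def total_scan_duration_us(config: ScanConfig) -> float:
    """Total acquisition time: rows x repeats x (cols x dwell + flyback)."""
    rows, _ = config.image_shape_px
    return rows * config.n_line_repeats * config.line_time_us
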