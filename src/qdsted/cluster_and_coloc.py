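"""Single-vs-cluster classification and endocytosis colocalization metrics.

The STEDonly image of a quantum dot is a donut (direct excitation by the
depletion beam): a *single* QD shows a central zero, while an unresolved
*cluster* of QDs fills the donut center because the member donuts overlap
at offsets below the resolution limit. The center-to-crest intensity
ratio therefore separates singles from clusters even when the STEDsub
image cannot.

On top of the classification this module computes the endocytosis
metrics: QDFI (fraction of QDs whose centers lie inside a vesicle mask),
SFP (single fraction parameter — ratio of the single-QD fraction inside a
vesicle class to that outside it; < 1 means relative clustering inside),
nearest-microtubule distances, and channel bleed-through ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import DegenerateInputError, InputError, UndefinedSFPError
from .qd_photophysics import QDRecord

__all__ = [
    "SceneMasks",
    "EndocytosisStats",
    "donut_central_ratio",
    "classify_multiplicity",
    "qd_fraction_inside",
    "compute_sfp",
    "distances_to_tubulin",
    "fraction_within",
    "bleedthrough_matrix",
    "make_structure_mask",
]


@dataclass
class SceneMasks:
    """Binary vesicle and tubulin masks on the analysed image grid."""

    vesicle_masks: dict[str, np.ndarray]
    tubulin_mask: np.ndarray | None
    pixel_size_nm: float

    def __post_init__(self) -> None:
        shapes = {k: np.asarray(v).shape for k, v in self.vesicle_masks.items()}
        if self.tubulin_mask is not None:
            shapes["tubulin"] = np.asarray(self.tubulin_mask).shape
        if len(set(shapes.values())) > 1:
            raise InputError(f"mask shapes differ: {shapes}")


@dataclass
class EndocytosisStats:
    """Aggregated per-scene colocalization results."""

    qdfi: dict[str, float]
    sfp: dict[str, float]
    distances_nm: np.ndarray
    fraction_within_200nm: float
    n_qds: int
    n_cells: int = 1


def donut_central_ratio(
    stedonly_roi: np.ndarray,
    center_px: tuple[float, float],
    inner_radius_px: float = 1.5,
    ring_radii_px: tuple[float, float] = (6.0, 10.0),
) -> float:
    """Center-to-crest intensity ratio of a QD's STEDonly donut.

    Mean background-subtracted counts within ``inner_radius_px`` of the
    center divided by the mean over the annulus ``ring_radii_px`` (placed
    on the donut crest). The background is the ROI border median, and
    means are floored at 0 before division. Near 0 for a single emitter,
    elevated for a cluster.
    """
    roi = np.asarray(stedonly_roi, dtype=float)
    r1, r2 = ring_radii_px
    if not 0 < inner_radius_px < r1 < r2:
        raise InputError("require 0 < inner_radius < ring r1 < r2")
    rr, cc = np.mgrid[0 : roi.shape[0], 0 : roi.shape[1]]
    dist = np.hypot(rr - center_px[0], cc - center_px[1])
    ring = (dist >= r1) & (dist <= r2)
    inner = dist <= inner_radius_px
    if ring.sum() < 8:
        raise InputError(f"annulus [{r1}, {r2}] px contains only {int(ring.sum())} pixels (< 8)")
    if inner.sum() == 0:
        raise InputError("inner disk contains no pixels")
    border = np.concatenate([roi[0, :], roi[-1, :], roi[1:-1, 0], roi[1:-1, -1]])
    bg = float(np.median(border))
    center_mean = max(float(roi[inner].mean()) - bg, 0.0)
    ring_mean = max(float(roi[ring].mean()) - bg, 0.0)
    if ring_mean == 0:
        raise DegenerateInputError("donut crest mean is zero after background subtraction")
    return center_mean / ring_mean


def classify_multiplicity(ratio: float, cutoff: float = 0.3) -> str:
    """``single`` iff the central ratio is at most the cutoff (ties single)."""
    if ratio < 0:
        raise InputError("central ratio must be >= 0")
    return "single" if ratio <= cutoff else "cluster"


def _centers_to_pixels(
    centers_nm: np.ndarray, pixel_size_nm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Map (x, y) centers in nm to containing (row, col) pixel indices."""
    c = np.asarray(centers_nm, dtype=float).reshape(-1, 2)
    cols = np.floor(c[:, 0] / pixel_size_nm).astype(int)
    rows = np.floor(c[:, 1] / pixel_size_nm).astype(int)
    return rows, cols


def qd_fraction_inside(
    qd_centers_nm: np.ndarray, mask: np.ndarray, pixel_size_nm: float,
    dilation_px: int = 0,
) -> float:
    """Fraction of QDs whose center falls in a true mask pixel (QDFI).

    Centers outside the image bounds count as outside the mask.
    ``dilation_px`` grows the mask before the membership test — useful for
    membrane labels (e.g. LAMP1 rings) whose lumen is unlabelled.
    """
    centers = np.asarray(qd_centers_nm, dtype=float).reshape(-1, 2)
    if centers.shape[0] == 0:
        raise DegenerateInputError("no QDs given")
    mask = np.asarray(mask, dtype=bool)
    if dilation_px > 0:
        from scipy.ndimage import binary_dilation
        from skimage.morphology import disk

        mask = binary_dilation(mask, structure=disk(dilation_px))
    rows, cols = _centers_to_pixels(centers, pixel_size_nm)
    in_bounds = (rows >= 0) & (rows < mask.shape[0]) & (cols >= 0) & (cols < mask.shape[1])
    inside = np.zeros(centers.shape[0], dtype=bool)
    inside[in_bounds] = mask[rows[in_bounds], cols[in_bounds]]
    return float(inside.mean())


def _single_fraction(records: Iterable) -> tuple[float, int]:
    labels = [
        r.multiplicity_class if isinstance(r, QDRecord) else str(r) for r in records
    ]
    if not labels:
        raise InputError("record list is empty")
    unknown = [l for l in labels if l not in ("single", "cluster")]
    if unknown:
        raise InputError(f"unclassified multiplicity labels present: {set(unknown)}")
    n_single = sum(1 for l in labels if l == "single")
    return n_single / len(labels), len(labels)


def compute_sfp(records_inside: Sequence, records_outside: Sequence) -> float:
    """Single fraction parameter: inside single fraction / outside single fraction.

    Accepts :class:`~qdsted.qd_photophysics.QDRecord` sequences or plain
    ``"single"``/``"cluster"`` label sequences. Raises
    :class:`UndefinedSFPError` when there are no single QDs outside (zero
    denominator), which must be reported rather than dropped.
    """
    f_in, _ = _single_fraction(records_inside)
    f_out, n_out = _single_fraction(records_outside)
    if f_out == 0:
        raise UndefinedSFPError(
            f"no single QDs among the {n_out} outside vesicles; SFP undefined"
        )
    return f_in / f_out


def distances_to_tubulin(
    qd_centers_nm: np.ndarray, tubulin_mask: np.ndarray, pixel_size_nm: float
) -> np.ndarray:
    """Distance (nm) from each QD center to the nearest tubulin pixel.

    A QD whose center lies in a true mask pixel is at distance 0 (it sits
    on the strand); otherwise the Euclidean distance to the nearest true
    pixel center is returned.
    """
    mask = np.asarray(tubulin_mask, dtype=bool)
    if not mask.any():
        raise InputError("tubulin mask has no true pixels")
    centers = np.asarray(qd_centers_nm, dtype=float).reshape(-1, 2)
    rows, cols = _centers_to_pixels(centers, pixel_size_nm)
    true_rc = np.argwhere(mask)
    true_xy = np.column_stack([(true_rc[:, 1] + 0.5), (true_rc[:, 0] + 0.5)]) * pixel_size_nm
    tree = cKDTree(true_xy)
    dist, _ = tree.query(centers)
    in_bounds = (rows >= 0) & (rows < mask.shape[0]) & (cols >= 0) & (cols < mask.shape[1])
    on_mask = np.zeros(centers.shape[0], dtype=bool)
    on_mask[in_bounds] = mask[rows[in_bounds], cols[in_bounds]]
    dist = np.where(on_mask, 0.0, dist)
    return dist.astype(float)


def fraction_within(distances_nm: np.ndarray, threshold_nm: float) -> float:
    """Fraction of distances strictly below the threshold."""
    d = np.asarray(distances_nm, dtype=float)
    if d.size == 0:
        raise DegenerateInputError("no distances given")
    return float((d < threshold_nm).mean())


def make_structure_mask(
    image: np.ndarray, min_area_px: int = 9, fill_holes: bool = True
) -> np.ndarray:
    """Otsu-threshold a dye channel into a binary structure mask.

    Thin configurable plumbing for callers without externally supplied
    masks: Otsu threshold, optional hole filling, small-object removal.
    """
    from scipy.ndimage import binary_fill_holes
    from skimage.filters import threshold_otsu
    from skimage.morphology import remove_small_objects

    img = np.asarray(image, dtype=float)
    mask = img > threshold_otsu(img)
    if fill_holes:
        mask = binary_fill_holes(mask)
    if min_area_px > 1:
        mask = remove_small_objects(mask, min_size=min_area_px)
    return mask


def bleedthrough_matrix(
    single_label_images: Mapping[str, Mapping[str, np.ndarray]],
    detection_masks: Mapping[str, np.ndarray],
    own_channel: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Bleed-through signal ratios from single-fluorophore acquisitions.

    ``single_label_images[f][c]`` is the image of fluorophore ``f`` (imaged
    alone) recorded in channel ``c``; ``detection_masks[f]`` marks ``f``'s
    structures. For each image the background (median outside the mask) is
    subtracted and the mean signal over the mask taken (floored at 0);
    ``ratio[f, c]`` is that signal in channel ``c`` divided by the signal
    in ``f``'s own channel. The diagonal is 1 by definition.
    """
    own_channel = dict(own_channel or {f: f for f in single_label_images})
    rows = {}
    for f, channel_images in single_label_images.items():
        mask = np.asarray(detection_masks[f], dtype=bool)
        if not mask.any():
            raise DegenerateInputError(f"detection mask for {f!r} is empty")
        own = own_channel[f]
        if own not in channel_images:
            raise InputError(f"own channel {own!r} missing for fluorophore {f!r}")

        def signal(img: np.ndarray) -> float:
            img = np.asarray(img, dtype=float)
            if img.shape != mask.shape:
                raise InputError(f"image/mask shape mismatch for {f!r}")
            outside = img[~mask]
            bg = float(np.median(outside)) if outside.size else 0.0
            return max(float(img[mask].mean()) - bg, 0.0)

        own_sig = signal(channel_images[own])
        if own_sig == 0:
            raise DegenerateInputError(f"fluorophore {f!r} has zero own-channel signal")
        row = {c: signal(img) / own_sig for c, img in channel_images.items()}
        row[own] = 1.0
        rows[f] = row
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()
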