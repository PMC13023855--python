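"""Anatomically constrained breast masking.

A simplified breast segmenter built from the standard operator classes used
for mammographic region extraction: intensity-based filtering (Otsu on a
smoothed image), morphological refinement (largest chest-wall-adjacent
component, closing, hole filling) and anatomical priors (chest-wall side
detection, optional straight-line pectoral removal on MLO views).  Masks
are always computed from the original, unenhanced image and applied to the
enhanced representation afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology, transform

from .io import GrayImage


class SegmentationError(RuntimeError):
    """Raised when no plausible breast region can be found."""


@dataclass(frozen=True)
class BreastMask:
    """Binary raster marking anatomically valid breast pixels.

    Invariants: exactly one 8-connected foreground component, touching the
    chest-wall border, with no holes.
    """

    pixels: np.ndarray
    chest_wall_side: str

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        if px.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.chest_wall_side not in ("left", "right"):
            raise ValueError("chest_wall_side must be 'left' or 'right'")
        if not px.any():
            raise ValueError("mask is empty")
        labels = measure.label(px, connectivity=2)
        if labels.max() != 1:
            raise ValueError(f"mask has {labels.max()} components, expected exactly 1")
        border_col = px[:, 0] if self.chest_wall_side == "left" else px[:, -1]
        if not border_col.any():
            raise ValueError("mask does not touch the chest-wall border")
        filled = ndimage.binary_fill_holes(px)
        if not np.array_equal(filled, px):
            raise ValueError("mask has holes")
        object.__setattr__(self, "pixels", px)

    @property
    def area(self) -> int:
        return int(self.pixels.sum())


def detect_chest_wall_side(img: GrayImage) -> str:
    """Side whose 5%-wide border column band has the higher mean intensity.

    Ties (exactly symmetric images) break toward 'left'.
    """
    px = img.pixels.astype(np.float64)
    band = max(1, round(0.05 * px.shape[1]))
    left = px[:, :band].mean()
    right = px[:, -band:].mean()
    return "right" if right > left else "left"


def _largest_adjacent_component(binary: np.ndarray, side: str) -> np.ndarray:
    labels = measure.label(binary, connectivity=2)
    if labels.max() == 0:
        raise SegmentationError("no breast tissue detected")
    border = labels[:, 0] if side == "left" else labels[:, -1]
    adjacent = np.unique(border[border > 0])
    candidates = adjacent if adjacent.size else np.arange(1, labels.max() + 1)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, candidates)
    best = candidates[int(np.argmax(sizes))]
    return labels == best


def segment_breast(img: GrayImage, view: str = "CC",
                   pectoral_removal: bool = True,
                   smoothing_sigma: float = 2.0) -> BreastMask:
    """Segment the breast region from an unenhanced image.

    Pipeline: Gaussian smoothing (2 px) -> Otsu threshold -> largest
    connected component adjacent to the chest-wall side -> morphological
    closing (disk radius 1% of width) -> hole fill -> optional pectoral
    removal on MLO views.
    """
    px = img.to_unit_float().pixels
    side = detect_chest_wall_side(img)
    smoothed = ndimage.gaussian_filter(px, sigma=smoothing_sigma)
    if smoothed.max() == smoothed.min():
        raise SegmentationError("no breast tissue detected")
    thresh = filters.threshold_otsu(smoothed)
    binary = smoothed > thresh
    if not binary.any():
        raise SegmentationError("no breast tissue detected")
    component = _largest_adjacent_component(binary, side)
    radius = max(1, round(0.01 * px.shape[1]))
    closed = morphology.closing(component, morphology.disk(radius)).astype(bool)
    filled = ndimage.binary_fill_holes(closed)
    # closing can merge satellites; keep the chest-wall component only
    filled = _largest_adjacent_component(filled, side)
    filled = ndimage.binary_fill_holes(filled)
    mask = BreastMask(filled, side)
    if view == "MLO" and pectoral_removal:
        mask = remove_pectoral(mask, img, view)
    return mask


def remove_pectoral(mask: BreastMask, img: GrayImage, view: str,
                    min_step: float = 0.05) -> BreastMask:
    """Subtract a straight-line pectoral-muscle estimate on MLO views.

    The boundary is fit through the steepest intensity-gradient ridge in the
    upper chest-wall quadrant; the triangle between the fitted line and the
    corner is removed.  When no sufficiently bright wedge exists (mean step
    across the candidate line below ``min_step`` on the unit scale) the mask
    is returned unchanged.  Non-MLO views pass through untouched.
    """
    if view != "MLO":
        return mask
    px = img.to_unit_float().pixels
    h, w = px.shape
    side = mask.chest_wall_side
    smoothed = ndimage.gaussian_filter(px, sigma=2.0)
    # work in chest-at-left orientation; mirror back at the end
    flip = side == "right"
    if flip:
        smoothed = smoothed[:, ::-1]
        mpx = mask.pixels[:, ::-1]
    else:
        mpx = mask.pixels

    rows = np.arange(0, int(0.55 * h))
    band = int(0.50 * w)
    grad = -np.diff(smoothed[:, :band], axis=1)  # positive where intensity drops l->r
    ridge_cols, ridge_rows = [], []
    for r in rows:
        row_in_mask = np.flatnonzero(mpx[r, :band])
        if row_in_mask.size < 4:
            continue
        g = grad[r, row_in_mask[0]: row_in_mask[-1]]
        if g.size == 0:
            continue
        c = row_in_mask[0] + int(np.argmax(g))
        if grad[r, c] > 0.01:
            ridge_rows.append(r)
            ridge_cols.append(c + 0.5)
    if len(ridge_rows) < max(5, 0.15 * len(rows)):
        return mask
    ridge_rows = np.asarray(ridge_rows, dtype=np.float64)
    ridge_cols = np.asarray(ridge_cols, dtype=np.float64)
    slope, intercept = np.polyfit(ridge_rows, ridge_cols, 1)
    if slope > -0.05:  # pectoral boundary must recede toward the chest wall
        return mask
    rr = np.arange(h)[:, None].astype(np.float64)
    cc = np.arange(w)[None, :].astype(np.float64)
    boundary = slope * rr + intercept
    wedge = (cc < boundary) & (rr[:, [0]] <= ridge_rows.max() + 2)
    inner, outer = wedge & mpx, ~wedge & mpx
    if not inner.any() or not outer.any():
        return mask
    if smoothed[inner].mean() - smoothed[outer].mean() < min_step:
        return mask
    new = mpx & ~wedge
    if flip:
        new = new[:, ::-1]
    new = _largest_adjacent_component(new, side)
    new = ndimage.binary_fill_holes(new)
    try:
        return BreastMask(new, side)
    except ValueError:
        return mask


def apply_mask(img: GrayImage, mask: BreastMask) -> GrayImage:
    """Zero every pixel outside the mask; inside pixels are untouched."""
    if img.pixels.shape != mask.pixels.shape:
        raise ValueError(
            f"image shape {img.pixels.shape} != mask shape {mask.pixels.shape}"
        )
    out = np.where(mask.pixels, img.pixels, 0)
    return GrayImage(out.astype(img.pixels.dtype), img.depth)


def resize_mask(mask: BreastMask, size: tuple[int, int]) -> BreastMask:
    """Nearest-neighbour resize so the mask stays binary."""
    if mask.pixels.shape == tuple(size):
        return mask
    out = transform.resize(mask.pixels.astype(np.float64), size, order=0,
                           anti_aliasing=False, preserve_range=True) > 0.5
    return BreastMask(out, mask.chest_wall_side)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|a∩b| / (|a|+|b|); two empty masks count as identical."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom
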