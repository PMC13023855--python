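"""The deterministic, label-independent enhancement chain.

Stages, in pipeline order: percentile windowing to [0, 1], 8-bit
quantization, global histogram matching against a dataset-level reference
CDF, local contrast mapping (unsharp-style high-pass), CLAHE, BayesShrink
wavelet denoising, and a final bilinear resize.  No stage ever sees a class
label; the only cross-image statistic is the reference CDF, which pools
intensity counts over the whole cohort after background exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pywt
from scipy import ndimage
from skimage import exposure, transform

from .io import GrayImage


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class WindowingParams:
    """Percentile clipping bounds (robust windowing)."""

    p_low: float = 5.0
    p_high: float = 99.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_low < self.p_high <= 100.0:
            raise ValueError(f"require 0 <= p_low < p_high <= 100, got ({self.p_low}, {self.p_high})")


@dataclass(frozen=True)
class LCMParams:
    """Gaussian scale of the smoothed copy subtracted by local contrast mapping."""

    sigma: float = 25.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass(frozen=True)
class CLAHEParams:
    """Contrast-limited adaptive equalization parameters.

    ``clip_limit`` follows the common histogram-multiple convention (2.0 by
    default); internally it is divided by the number of bins (256) to obtain
    the normalized clip fraction scikit-image expects.
    """

    clip_limit: float = 2.0
    tile_grid: tuple[int, int] = (8, 8)

    def __post_init__(self) -> None:
        if self.clip_limit <= 0:
            raise ValueError("clip_limit must be > 0")
        if min(self.tile_grid) < 1:
            raise ValueError("tile_grid entries must be >= 1")


@dataclass(frozen=True)
class DenoiseParams:
    """BayesShrink soft-threshold wavelet denoising parameters."""

    wavelet: str = "db1"
    levels: int = 2
    threshold_mode: str = "soft"
    method: str = "bayes"
    sigma_rescale: bool = True

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.threshold_mode != "soft":
            raise ValueError("only soft thresholding is supported")
        if self.method != "bayes":
            raise ValueError("only BayesShrink threshold estimation is supported")
        if self.wavelet not in pywt.wavelist(kind="discrete"):
            raise ValueError(f"unknown discrete wavelet {self.wavelet!r}")


@dataclass(frozen=True)
class ReferenceCDF:
    """Dataset-level cumulative intensity distribution over 256 levels."""

    cdf: np.ndarray
    background_rule: str = "none"

    def __post_init__(self) -> None:
        cdf = np.asarray(self.cdf, dtype=np.float64)
        if cdf.shape != (256,):
            raise ValueError("reference CDF must have 256 levels")
        if np.any(np.diff(cdf) < -1e-12):
            raise ValueError("reference CDF must be nondecreasing")
        if abs(cdf[-1] - 1.0) > 1e-9:
            raise ValueError("reference CDF must end at 1")
        object.__setattr__(self, "cdf", cdf)

    @property
    def levels(self) -> np.ndarray:
        return np.arange(256)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"level": self.levels, "cdf": self.cdf}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, background_rule: str = "unknown") -> "ReferenceCDF":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["cdf"].to_numpy(), background_rule)


def resolve_background_rule(rule: str) -> Callable[[np.ndarray], np.ndarray]:
    """Turn a background-rule spec into an exclusion predicate on u8 pixels.

    ``"none"`` keeps everything; ``"intensity_lt:K"`` excludes pixels with
    intensity below K (near-black air around the breast).
    """
    if rule == "none":
        return lambda px: np.zeros_like(px, dtype=bool)
    if rule.startswith("intensity_lt:"):
        k = int(rule.split(":", 1)[1])
        return lambda px: px < k
    raise ValueError(f"unknown background rule {rule!r}")


DEFAULT_BACKGROUND_RULE = "intensity_lt:2"


# ---------------------------------------------------------------------------
# stages


def percentile_window(img: GrayImage, params: WindowingParams = WindowingParams()) -> GrayImage:
    """Clip to the [p_low, p_high] empirical percentiles and rescale to [0, 1].

    Percentiles use the linear-interpolation definition.  A constant image
    (degenerate window) maps to all zeros.
    """
    px = img.pixels.astype(np.float64)
    lo, hi = np.percentile(px, [params.p_low, params.p_high], method="linear")
    if hi <= lo:
        return GrayImage(np.zeros_like(px), "unit_float")
    out = (np.clip(px, lo, hi) - lo) / (hi - lo)
    return GrayImage(out, "unit_float")


def to_uint8(img: GrayImage) -> GrayImage:
    """Quantize unit_float to u8 with the symmetric rule v -> floor(255 v + 0.5)."""
    if img.depth != "unit_float":
        raise ValueError("to_uint8 expects a unit_float image")
    out = np.floor(255.0 * img.pixels + 0.5).astype(np.uint8)
    return GrayImage(out, "u8")


def build_reference_cdf(images: Sequence[GrayImage],
                        background_rule: str = DEFAULT_BACKGROUND_RULE) -> ReferenceCDF:
    """Pool u8 histograms over all images (minus excluded background pixels).

    Summation over pooled counts makes the result independent of input
    order.  Raises if the rule excludes every pixel.
    """
    if len(images) == 0:
        raise ValueError("need at least one image")
    exclude = resolve_background_rule(background_rule)
    counts = np.zeros(256, dtype=np.int64)
    for img in images:
        if img.depth != "u8":
            raise ValueError("reference CDF is built on u8 images")
        keep = ~exclude(img.pixels)
        counts += np.bincount(img.pixels[keep].ravel(), minlength=256)
    total = counts.sum()
    if total == 0:
        raise ValueError("background rule excluded every pixel; cannot build reference CDF")
    cdf = np.cumsum(counts) / total
    cdf[-1] = 1.0
    return ReferenceCDF(cdf, background_rule)


def histogram_matching_lut(img: GrayImage, ref: ReferenceCDF) -> np.ndarray:
    """Monotone 256-entry LUT mapping source levels onto the reference CDF.

    The source CDF is built under the same background rule the reference was
    built with; level v maps to min{u : ref.cdf[u] >= F(v)}.
    """
    if img.depth != "u8":
        raise ValueError("histogram matching operates on u8 images")
    exclude = resolve_background_rule(ref.background_rule)
    keep = ~exclude(img.pixels)
    vals = img.pixels[keep] if keep.any() else img.pixels
    counts = np.bincount(vals.ravel(), minlength=256)
    src_cdf = np.cumsum(counts) / counts.sum()
    lut = np.searchsorted(ref.cdf, src_cdf, side="left")
    return np.clip(lut, 0, 255).astype(np.uint8)


def match_histogram(img: GrayImage, ref: ReferenceCDF) -> GrayImage:
    """Apply the CDF-to-CDF lookup pixelwise (background pixels included)."""
    lut = histogram_matching_lut(img, ref)
    return GrayImage(lut[img.pixels], "u8")


def local_contrast_map(img: GrayImage, params: LCMParams = LCMParams()) -> GrayImage:
    """High-pass residual against a Gaussian-smoothed copy, min-max rescaled.

    Reflect padding at the boundary; a constant residual maps to zeros.
    """
    if img.depth != "unit_float":
        raise ValueError("local_contrast_map expects a unit_float image")
    smoothed = ndimage.gaussian_filter(img.pixels, sigma=params.sigma, mode="reflect")
    d = img.pixels - smoothed
    span = d.max() - d.min()
    if span <= 0:
        return GrayImage(np.zeros_like(d), "unit_float")
    return GrayImage((d - d.min()) / span, "unit_float")


def clahe(img: GrayImage, params: CLAHEParams = CLAHEParams(),
          min_tile_px: int = 32) -> GrayImage:
    """Contrast-limited adaptive histogram equalization on a u8 image.

    Tiles are clamped to at least ``min_tile_px`` on each side: below that
    the integer per-bin clip count collapses to its floor and the configured
    clip limit silently stops limiting anything, so small working
    resolutions would get maximal (unlimited) equalization instead of the
    configured behavior.
    """
    if img.depth != "u8":
        raise ValueError("clahe expects a u8 image")
    px = img.pixels
    if px.max() == px.min():
        return GrayImage(px.copy(), "u8")
    kernel = (min(px.shape[0], max(min_tile_px, px.shape[0] // params.tile_grid[0])),
              min(px.shape[1], max(min_tile_px, px.shape[1] // params.tile_grid[1])))
    out = exposure.equalize_adapthist(px, kernel_size=kernel,
                                      clip_limit=params.clip_limit / 256.0, nbins=256)
    return to_uint8(GrayImage(out, "unit_float"))


def estimate_noise_sigma(img: GrayImage, wavelet: str = "db1") -> float:
    """Robust noise estimate: median(|HH1|) / 0.6745 from a one-level DWT."""
    if img.depth != "unit_float":
        raise ValueError("estimate_noise_sigma expects a unit_float image")
    _, (_, _, hh) = pywt.dwt2(img.pixels, wavelet)
    return float(np.median(np.abs(hh)) / 0.6745)


def _bayes_threshold(subband: np.ndarray, sigma_n: float) -> float | None:
    """BayesShrink threshold T = sigma_n^2 / sigma_x; None means zero the subband."""
    sigma_y2 = float(np.mean(subband**2))
    sigma_x = np.sqrt(max(sigma_y2 - sigma_n**2, 0.0))
    if sigma_x == 0.0:
        return None
    return sigma_n**2 / sigma_x


def soft_threshold(coeffs: np.ndarray, t: float) -> np.ndarray:
    """sign(c) * max(|c| - t, 0)."""
    return np.sign(coeffs) * np.maximum(np.abs(coeffs) - t, 0.0)


def wavelet_denoise(img: GrayImage, params: DenoiseParams = DenoiseParams(),
                    sigma: float | None = None) -> GrayImage:
    """Multilevel BayesShrink soft-threshold denoising.

    The noise scale is estimated once from the finest-level diagonal subband
    (when ``sigma_rescale`` is set and no explicit sigma is given) and reused
    for every detail subband; a subband whose energy does not exceed the
    noise floor is zeroed entirely.  Output is clipped back to [0, 1].
    """
    if img.depth != "unit_float":
        raise ValueError("wavelet_denoise expects a unit_float image")
    if min(img.pixels.shape) < 2**params.levels:
        raise ValueError(
            f"image of shape {img.pixels.shape} too small for {params.levels} decomposition levels"
        )
    if sigma is None:
        if not params.sigma_rescale:
            raise ValueError("pass an explicit sigma when sigma_rescale is disabled")
        sigma_n = estimate_noise_sigma(img, params.wavelet)
    else:
        sigma_n = float(sigma)

    coeffs = pywt.wavedec2(img.pixels, params.wavelet, level=params.levels)
    new_coeffs = [coeffs[0]]
    for detail in coeffs[1:]:
        shrunk = []
        for sub in detail:
            t = _bayes_threshold(sub, sigma_n)
            shrunk.append(np.zeros_like(sub) if t is None else soft_threshold(sub, t))
        new_coeffs.append(tuple(shrunk))
    out = pywt.waverec2(new_coeffs, params.wavelet)
    out = out[: img.pixels.shape[0], : img.pixels.shape[1]]
    return GrayImage(np.clip(out, 0.0, 1.0), "unit_float")


def resize(img: GrayImage, size: tuple[int, int] = (224, 224)) -> GrayImage:
    """Bilinear resize without aspect preservation; depth is preserved.

    Masks and other binary rasters should be resized with order-0
    interpolation instead (see :func:`resize_mask` in breastmask).
    """
    if img.pixels.shape == tuple(size):
        return img
    out = transform.resize(img.pixels.astype(np.float64), size, order=1,
                           anti_aliasing=False, preserve_range=True)
    if img.depth == "unit_float":
        return GrayImage(np.clip(out, 0.0, 1.0), "unit_float")
    hi = 255 if img.depth == "u8" else 65535
    return GrayImage(np.clip(np.round(out), 0, hi), img.depth)


# ---------------------------------------------------------------------------
# full chain


@dataclass(frozen=True)
class EnhanceConfig:
    """Flat configuration for the enhancement chain.

    The Gaussian scale of local contrast mapping defaults to 25 px at a
    512-px working width and is scaled proportionally with the actual image
    width.  Individual stages can be disabled; windowing and the final
    resize always run.
    """

    windowing: WindowingParams = WindowingParams()
    lcm: LCMParams = LCMParams()
    clahe_params: CLAHEParams = CLAHEParams()
    denoise: DenoiseParams = DenoiseParams()
    do_hist_match: bool = True
    do_lcm: bool = True
    do_clahe: bool = True
    do_denoise: bool = True
    lcm_sigma_reference_width: int = 512
    out_size: tuple[int, int] = (224, 224)


def preprocess_image(img: GrayImage, config: EnhanceConfig = EnhanceConfig(),
                     ref: ReferenceCDF | None = None) -> GrayImage:
    """Run the full chain on one image; returns a u8 image at ``out_size``.

    Order: windowing -> u8 -> histogram matching -> local contrast mapping ->
    CLAHE -> wavelet denoising -> u8 -> resize.  Breast masking, when
    requested, is applied downstream on the result.
    """
    x = percentile_window(img, config.windowing)
    x = to_uint8(x)
    if config.do_hist_match:
        if ref is None:
            raise ValueError("histogram matching enabled but no reference CDF given")
        x = match_histogram(x, ref)
    if config.do_lcm:
        sigma = config.lcm.sigma * img.width / config.lcm_sigma_reference_width
        x = local_contrast_map(x.to_unit_float(), LCMParams(sigma=max(sigma, 0.5)))
        x = to_uint8(x)
    if config.do_clahe:
        x = clahe(x, config.clahe_params)
    if config.do_denoise:
        x = wavelet_denoise(x.to_unit_float(), config.denoise)
        x = to_uint8(x)
    return resize(x, config.out_size)
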