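"""Pore-size quantification of grayscale fiber-matrix reflection images.

Confocal reflection images of collagen matrices show bright fibers and dark
interstitial pores.  The chain is: divide out a wide-Gaussian estimate of the
illumination field and rescale to unit mean; threshold the normalized image
(Otsu by default) so the darkest regions form a binary pore mask; label
8-connected components, discard border-touching components (truncated pores)
and fragments below a minimum area; and report each pore's equivalent-area
diameter, 2*sqrt(area/pi), in pixels and, when a pixel size is given, in
micrometres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure, segmentation

__all__ = [
    "PoreImage",
    "PoreStats",
    "normalize_illumination",
    "segment_pores",
    "pore_diameters",
    "analyze_pores",
]

MIN_PORE_AREA_PX = 4


@dataclass(frozen=True)
class PoreImage:
    """2D grayscale image, optionally calibrated (um per pixel)."""

    pixels: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or min(px.shape) < 32:
            raise ValueError("image must be 2D and at least 32x32 pixels")
        if not np.isfinite(px).all():
            raise ValueError("image intensities must be finite")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class PoreStats:
    """Per-pore equivalent diameters plus mask coverage."""

    diameters_px: np.ndarray
    diameters_um: np.ndarray | None
    pore_count: int
    coverage: float  # fraction of pixels inside retained pores


def normalize_illumination(img: PoreImage, background_scale: float = 64.0) -> PoreImage:
    """Divide out a smooth large-scale background and rescale to unit mean.

    The background is the image blurred with a Gaussian of width
    ``background_scale`` pixels (>= 8), wide enough to smooth over fibers and
    pores but follow slow illumination drifts.
    """
    if background_scale < 8:
        raise ValueError("background_scale must be >= 8 px")
    px = img.pixels
    if np.all(px == 0):
        raise ValueError("degenerate image: all intensities are zero")
    background = ndimage.gaussian_filter(px, sigma=background_scale, mode="reflect")
    background = np.where(background <= 0, np.finfo(float).tiny, background)
    flat = px / background
    return PoreImage(flat / flat.mean(), pixel_size=img.pixel_size)


def segment_pores(
    img: PoreImage,
    method: str = "otsu",
    quantile: float = 0.15,
    min_area: int = MIN_PORE_AREA_PX,
) -> np.ndarray:
    """Label the dark (below-threshold) regions of a normalized image.

    ``method`` is "otsu" (parameter-free) or "quantile" (threshold at the
    given intensity quantile).  Components are 8-connected; those touching
    the image border or smaller than ``min_area`` pixels are discarded.
    Returns the labeled integer mask (0 = background).
    """
    px = img.pixels
    if method == "otsu":
        thr = filters.threshold_otsu(px)
    elif method == "quantile":
        thr = np.quantile(px, quantile)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    mask = px < thr
    labels = measure.label(mask, connectivity=2)
    labels = segmentation.clear_border(labels)
    # drop fragments below the minimum area
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < min_area)
    labels[np.isin(labels, small)] = 0
    labels, n_found = measure.label(labels > 0, connectivity=2, return_num=True)
    if n_found == 0:
        warnings.warn("pore mask is empty after filtering")
    return labels


def pore_diameters(labels: np.ndarray, pixel_size: float | None = None) -> PoreStats:
    """Equivalent-area diameter, 2*sqrt(area/pi), of each labeled pore."""
    props = measure.regionprops(labels)
    d_px = np.array(sorted(p.equivalent_diameter_area for p in props))
    d_um = d_px * pixel_size if pixel_size is not None else None
    coverage = float((labels > 0).mean())
    return PoreStats(
        diameters_px=d_px,
        diameters_um=d_um,
        pore_count=len(d_px),
        coverage=coverage,
    )


def analyze_pores(
    img: PoreImage,
    background_scale: float = 64.0,
    method: str = "otsu",
    quantile: float = 0.15,
    min_area: int = MIN_PORE_AREA_PX,
) -> PoreStats:
    """Full chain: illumination normalization, masking, diameter measurement."""
    flat = normalize_illumination(img, background_scale)
    labels = segment_pores(flat, method=method, quantile=quantile, min_area=min_area)
    return pore_diameters(labels, pixel_size=img.pixel_size)
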