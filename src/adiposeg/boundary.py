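"""Tissue-background surface detection and boundary masking of seeds.

CAMs respond strongly to the bright artifact band at the tissue surface, so
adipose seeds at or above the surface are unreliable. This module finds the
per-column surface row with a smoothed-threshold first-crossing detector
(Otsu threshold over the image, depth-smoothed columns, column-wise median
filter) and removes seeds above or within a configurable margin of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d, median_filter
from skimage.filters import threshold_otsu

from .interface import BScan

__all__ = ["SurfaceBoundary", "NoSurfaceError", "detect_surface", "mask_seeds"]

MEDIAN_WINDOW = 15  # columns, for smoothing the detected surface


class NoSurfaceError(ValueError):
    """Raised when no tissue surface can be found in any column."""


@dataclass(frozen=True)
class SurfaceBoundary:
    """Per-column integer row index of the first tissue pixel."""

    surface_row: np.ndarray  # shape (width,), int

    def __post_init__(self) -> None:
        if self.surface_row.ndim != 1:
            raise ValueError("surface_row must be one row index per column")

    @property
    def width(self) -> int:
        return self.surface_row.shape[0]


def detect_surface(image: BScan | np.ndarray, smooth_sigma: float = 3.0,
                   min_jump: float = 0.0) -> SurfaceBoundary:
    """Locate the tissue-background interface in a B-scan.

    Per column, the surface is the first row where the depth-smoothed
    intensity exceeds an adaptive (Otsu) threshold computed over the whole
    image; the resulting curve is median-filtered across columns (window
    15). Columns with no crossing inherit the nearest detected column's
    value. ``min_jump`` raises the threshold floor for very clean images.

    Raises :class:`NoSurfaceError` if no column crosses the threshold.
    """
    px = image.pixels if isinstance(image, BScan) else np.asarray(image)
    smoothed = gaussian_filter1d(px.astype(np.float64), smooth_sigma, axis=0,
                                 mode="nearest")
    lo, hi = float(px.min()), float(px.max())
    if hi - lo < 1e-9:
        raise NoSurfaceError("image is constant; no tissue surface")
    thresh = max(float(threshold_otsu(smoothed)), lo + min_jump)
    above = smoothed > thresh
    has_tissue = above.any(axis=0)
    if not has_tissue.any():
        raise NoSurfaceError("no column exceeds the tissue threshold")
    first = np.where(has_tissue, above.argmax(axis=0), -1)
    cols = np.arange(px.shape[1])
    if (~has_tissue).any():
        good = cols[has_tissue]
        first = first.copy()
        first[~has_tissue] = first[good[
            np.abs(good[None, :] - cols[~has_tissue, None]).argmin(axis=1)]]
    surface = median_filter(first.astype(np.int64), size=MEDIAN_WINDOW,
                            mode="nearest")
    surface = np.clip(surface, 0, px.shape[0] - 1)
    return SurfaceBoundary(surface_row=surface)


def mask_seeds(seeds: np.ndarray, surface: SurfaceBoundary,
               margin: int = 10) -> np.ndarray:
    """Keep only seeds strictly below ``surface_row + margin`` in their column.

    The result is a subset of the input seeds; applying the mask twice is a
    no-op.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    seeds = np.asarray(seeds)
    if seeds.shape[1] != surface.width:
        raise ValueError("seed map width does not match surface width")
    rows = np.arange(seeds.shape[0])[:, None]
    keep = rows > (surface.surface_row[None, :] + margin)
    return (seeds.astype(bool) & keep).astype(np.uint8)


def surface_to_csv(surface: SurfaceBoundary, path) -> None:
    """One-row-per-column CSV export for inspection."""
    import pandas as pd

    pd.DataFrame({"column": np.arange(surface.width),
                  "surface_row": surface.surface_row}).to_csv(path, index=False)
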