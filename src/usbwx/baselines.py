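"""Histogram-based contrast enhancement baselines: HE and CLAHE.

These are the classical comparators for the learned restoration: global
histogram equalization, and contrast-limited adaptive histogram equalization
implemented as its four canonical steps - partition into non-overlapping
tiles, clip each tile histogram above a threshold and redistribute the
clipped mass across all gray values, equalize each tile, and bilinearly
interpolate the per-tile mappings.  With a single tile and no clipping,
CLAHE degenerates to HE pixelwise; that equivalence is part of the contract
and is why the two share one binning/CDF convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .bmode import BModeImage

__all__ = ["ClaheConfig", "hist_eq", "clahe"]


@dataclass(frozen=True)
class ClaheConfig:
    """tile_grid (rows, cols); clip_limit as a fraction of the per-tile pixel
    count above which histogram bins are clipped (np.inf disables clipping);
    n_bins gray-level resolution."""

    tile_grid: tuple[int, int] = (8, 8)
    clip_limit: float = 0.01
    n_bins: int = 256

    def __post_init__(self):
        if min(self.tile_grid) < 1:
            raise ValueError("tile grid must be at least (1, 1)")
        if self.clip_limit <= 0:
            raise ValueError("clip limit must be positive")
        if self.n_bins < 2:
            raise ValueError("need at least two bins")


def _as_array(image) -> tuple[np.ndarray, float]:
    if isinstance(image, BModeImage):
        return image.pixels.astype(np.float64), image.dynamic_range_db
    arr = np.asarray(image, np.float64)
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("image must lie in [0, 1]")
    return arr, 60.0


def _quantize(arr: np.ndarray, n_bins: int) -> np.ndarray:
    return np.minimum((arr * n_bins).astype(np.int64), n_bins - 1)


def _cdf_map(bins: np.ndarray, n_bins: int) -> np.ndarray:
    """Empirical-CDF lookup table over gray levels (maps level -> CDF)."""
    counts = np.bincount(bins.ravel(), minlength=n_bins)
    cdf = np.cumsum(counts) / bins.size
    return cdf


def hist_eq(image, n_bins: int = 256) -> BModeImage:
    """Global histogram equalization: p -> empirical CDF(p) on n_bins levels."""
    arr, dr = _as_array(image)
    bins = _quantize(arr, n_bins)
    if bins.min() == bins.max():
        warnings.warn("constant image: histogram equalization is the identity")
        return BModeImage(arr.astype(np.float32), dr, "he")
    out = _cdf_map(bins, n_bins)[bins]
    return BModeImage(out.astype(np.float32), dr, "he")


def clip_histogram(counts: np.ndarray, clip_count: float) -> np.ndarray:
    """Clip bins above the threshold, redistributing the excess uniformly.

    One redistribution pass; the per-bin remainder after redistribution is
    below one count, matching the 'distribute to all the gray values' step.
    """
    if not np.isfinite(clip_count):
        return counts.astype(np.float64)
    counts = counts.astype(np.float64)
    excess = np.maximum(counts - clip_count, 0.0).sum()
    clipped = np.minimum(counts, clip_count)
    return clipped + excess / counts.size


def clahe(image, config: ClaheConfig = ClaheConfig()) -> BModeImage:
    """Contrast-limited adaptive histogram equalization (four-step form)."""
    arr, dr = _as_array(image)
    rows, cols = config.tile_grid
    h, w = arr.shape
    if h // rows < 2 or w // cols < 2:
        raise ValueError("tiles smaller than 2x2 pixels")
    nb = config.n_bins
    bins = _quantize(arr, nb)
    r_edges = np.linspace(0, h, rows + 1).astype(int)
    c_edges = np.linspace(0, w, cols + 1).astype(int)

    # per-tile clipped-and-equalized mappings (level -> [0, 1])
    maps = np.empty((rows, cols, nb))
    centers_r = np.empty(rows)
    centers_c = np.empty(cols)
    for i in range(rows):
        for j in range(cols):
            tile = bins[r_edges[i]:r_edges[i + 1], c_edges[j]:c_edges[j + 1]]
            counts = np.bincount(tile.ravel(), minlength=nb)
            clip_count = config.clip_limit * tile.size
            clipped = clip_histogram(counts, clip_count)
            maps[i, j] = np.cumsum(clipped) / clipped.sum()
        centers_r[i] = (r_edges[i] + r_edges[i + 1] - 1) / 2.0
    for j in range(cols):
        centers_c[j] = (c_edges[j] + c_edges[j + 1] - 1) / 2.0

    # bilinear interpolation of the tile mappings at every pixel
    rr = np.arange(h, dtype=np.float64)
    cc = np.arange(w, dtype=np.float64)
    ri = np.clip(np.searchsorted(centers_r, rr) - 1, 0, max(rows - 2, 0))
    ci = np.clip(np.searchsorted(centers_c, cc) - 1, 0, max(cols - 2, 0))
    if rows > 1:
        tr = np.clip((rr - centers_r[ri]) / (centers_r[ri + 1] - centers_r[ri]), 0, 1)
    else:
        ri = np.zeros(h, int)
        tr = np.zeros(h)
    if cols > 1:
        tc = np.clip((cc - centers_c[ci]) / (centers_c[ci + 1] - centers_c[ci]), 0, 1)
    else:
        ci = np.zeros(w, int)
        tc = np.zeros(w)

    ri2 = np.minimum(ri + 1, rows - 1)
    ci2 = np.minimum(ci + 1, cols - 1)
    RI, CI = np.meshgrid(ri, ci, indexing="ij")
    RI2, CI2 = np.meshgrid(ri2, ci2, indexing="ij")
    TR = tr[:, None]
    TC = tc[None, :]
    v00 = maps[RI, CI, bins]
    v01 = maps[RI, CI2, bins]
    v10 = maps[RI2, CI, bins]
    v11 = maps[RI2, CI2, bins]
    out = ((1 - TR) * (1 - TC) * v00 + (1 - TR) * TC * v01
           + TR * (1 - TC) * v10 + TR * TC * v11)
    return BModeImage(np.clip(out, 0, 1).astype(np.float32), dr, "clahe")
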