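"""Contrast-limited adaptive histogram equalization (CLAHE).

The image is divided into a grid of contextual regions; each region's
256-bin histogram is clipped at ``clip`` x (region pixel count), the
clipped-off mass is redistributed uniformly over the remaining headroom
(iterated until it is fully conserved), and the per-region mapping is the
cumulative histogram scaled to [0, 255].  Pixel values are bilinearly
interpolated between the four neighbouring region mappings, with edge
regions extended by clamping, which removes tile seams.

With a single tile and clip=1 the procedure reduces exactly to plain
global histogram equalization.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError
from .io import as_gray_image

N_LEVELS = 256


def clip_histogram(hist: np.ndarray, clip_value: int) -> np.ndarray:
    """Clip a histogram at ``clip_value`` and redistribute the excess.

    Redistribution is uniform over the bins still below the clip level,
    iterated until every clipped-off count has been placed; total mass is
    conserved exactly.  ``clip_value`` must permit a feasible result
    (clip_value * n_bins >= total mass).
    """
    h = np.asarray(hist, dtype=np.int64).copy()
    if clip_value < 1:
        raise ParameterError("clip_value must be >= 1")
    excess = int(np.maximum(h - clip_value, 0).sum())
    h = np.minimum(h, clip_value)
    while excess > 0:
        under = np.flatnonzero(h < clip_value)
        if under.size == 0:
            raise ParameterError("clip level infeasible: cannot conserve mass")
        share = excess // under.size
        if share == 0:
            h[under[:excess]] += 1
            excess = 0
        else:
            add = np.minimum(share, clip_value - h[under])
            h[under] += add
            excess -= int(add.sum())
    return h


def _tile_mapping(tile: np.ndarray, clip: float) -> np.ndarray:
    npx = tile.size
    hist = np.bincount(tile.ravel(), minlength=N_LEVELS)
    # feasibility floor: a clip below the uniform level cannot conserve mass
    clip_value = max(int(np.ceil(clip * npx)), int(np.ceil(npx / N_LEVELS)))
    hist = clip_histogram(hist, clip_value)
    cdf = np.cumsum(hist)
    return np.rint(cdf * (N_LEVELS - 1) / npx).astype(np.float64)


def histogram_equalize(image) -> np.ndarray:
    """Plain global histogram equalization (CDF mapping scaled to [0, 255])."""
    img = as_gray_image(image)
    cdf = np.cumsum(np.bincount(img.ravel(), minlength=N_LEVELS))
    lut = np.rint(cdf * (N_LEVELS - 1) / img.size).astype(np.uint8)
    return lut[img]


def clahe(image, tiles: tuple[int, int] = (8, 8), clip: float = 0.01) -> np.ndarray:
    """Apply CLAHE with a ``tiles`` = (rows, cols) region grid and clip fraction."""
    img = as_gray_image(image)
    h, w = img.shape
    tr, tc = int(tiles[0]), int(tiles[1])
    if tr < 1 or tc < 1:
        raise ParameterError("tiles must be >= (1, 1)")
    if tr > h or tc > w:
        raise ParameterError(f"tile grid {tiles} larger than image {img.shape}")
    if not 0 < clip <= 1:
        raise ParameterError("clip must lie in (0, 1]")

    row_edges = np.rint(np.linspace(0, h, tr + 1)).astype(int)
    col_edges = np.rint(np.linspace(0, w, tc + 1)).astype(int)
    maps = np.empty((tr, tc, N_LEVELS), dtype=np.float64)
    for i in range(tr):
        for j in range(tc):
            tile = img[row_edges[i] : row_edges[i + 1], col_edges[j] : col_edges[j + 1]]
            maps[i, j] = _tile_mapping(tile, clip)

    # bilinear interpolation between the four neighbouring tile mappings
    centers_r = (row_edges[:-1] + row_edges[1:] - 1) / 2.0
    centers_c = (col_edges[:-1] + col_edges[1:] - 1) / 2.0

    def _coords(pix: np.ndarray, centers: np.ndarray):
        hi = np.searchsorted(centers, pix)
        lo = np.clip(hi - 1, 0, centers.size - 1)
        hi = np.clip(hi, 0, centers.size - 1)
        span = centers[hi] - centers[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            wgt = np.where(span > 0, (pix - centers[lo]) / np.where(span > 0, span, 1), 0.0)
        return lo, hi, np.clip(wgt, 0.0, 1.0)

    r = np.arange(h, dtype=np.float64)
    c = np.arange(w, dtype=np.float64)
    r0, r1, wr = _coords(r, centers_r)
    c0, c1, wc = _coords(c, centers_c)

    r0g, r1g = r0[:, None], r1[:, None]
    c0g, c1g = c0[None, :], c1[None, :]
    wrg, wcg = wr[:, None], wc[None, :]

    v00 = maps[r0g, c0g, img]
    v01 = maps[r0g, c1g, img]
    v10 = maps[r1g, c0g, img]
    v11 = maps[r1g, c1g, img]
    out = (
        (1 - wrg) * ((1 - wcg) * v00 + wcg * v01)
        + wrg * ((1 - wcg) * v10 + wcg * v11)
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)
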