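"""Contrast-limited adaptive histogram equalization on 8-bit images.

Tile-based CLAHE with the integer LUT semantics common in C++ imaging
libraries: each tile's 256-bin histogram is clipped at
``clip_limit * tile_area / 256`` counts (minimum 1), the clipped excess is
redistributed uniformly over all bins, and the tile's mapping is
``round(255 * cdf)``.  Pixel values are then mapped by bilinear interpolation
between the LUTs of the four tiles whose centers surround the pixel, with
border replication outside the outermost tile centers.  A 1x1 tile grid with
an unbounded clip limit therefore reduces exactly to global histogram
equalization.
"""

from __future__ import annotations

import math

import numpy as np

from .exceptions import ValidationError


def _tile_edges(size: int, ntiles: int) -> np.ndarray:
    # near-equal integer tiles covering [0, size)
    return np.array([size * i // ntiles for i in range(ntiles + 1)], dtype=np.int64)


def tile_luts(img: np.ndarray, tile_grid: tuple[int, int], clip_limit: float | None) -> np.ndarray:
    """Per-tile 8-bit lookup tables, shape ``(tiles_y, tiles_x, 256)``."""
    h, w = img.shape
    ty, tx = tile_grid
    ey, ex = _tile_edges(h, ty), _tile_edges(w, tx)
    luts = np.empty((ty, tx, 256), dtype=np.uint8)
    for i in range(ty):
        for j in range(tx):
            tile = img[ey[i]:ey[i + 1], ex[j]:ex[j + 1]]
            area = tile.size
            hist = np.bincount(tile.ravel(), minlength=256).astype(np.int64)
            if clip_limit is not None and math.isfinite(clip_limit):
                cap = max(int(clip_limit * area / 256.0), 1)
                excess = int(np.sum(np.maximum(hist - cap, 0)))
                if excess:
                    hist = np.minimum(hist, cap)
                    hist += excess // 256
                    hist[: excess % 256] += 1
            lut = np.rint(np.cumsum(hist) * (255.0 / area))
            luts[i, j] = np.clip(lut, 0, 255).astype(np.uint8)
    return luts


def _interp_coords(size: int, ntiles: int):
    """Bracketing tile indices and fractional weights for every coordinate."""
    edges = _tile_edges(size, ntiles)
    centers = (edges[:-1] + edges[1:] - 1) / 2.0
    pos = np.arange(size, dtype=np.float64)
    j = np.searchsorted(centers, pos, side="left")
    i0 = np.clip(j - 1, 0, ntiles - 1)
    i1 = np.clip(j, 0, ntiles - 1)
    denom = centers[i1] - centers[i0]
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom > 0, (pos - centers[i0]) / np.where(denom > 0, denom, 1.0), 0.0)
    return i0, i1, w


def clahe(img: np.ndarray, tile_grid: tuple[int, int] = (8, 8),
          clip_limit: float | None = 40.0) -> np.ndarray:
    """Apply CLAHE to an 8-bit image; returns a new 8-bit image."""
    img = np.asarray(img)
    if img.ndim != 2 or img.dtype != np.uint8:
        raise ValidationError("clahe expects a 2-D uint8 image")
    h, w = img.shape
    ty, tx = int(tile_grid[0]), int(tile_grid[1])
    if ty < 1 or tx < 1:
        raise ValidationError(f"tile grid dims must be >= 1, got {tile_grid}")
    if ty > h or tx > w:
        raise ValidationError(
            f"tile grid {tile_grid} larger than image {img.shape}"
        )

    luts = tile_luts(img, (ty, tx), clip_limit)
    iy0, iy1, wy = _interp_coords(h, ty)
    ix0, ix1, wx = _interp_coords(w, tx)

    # gather the four surrounding tile mappings for every pixel
    l00 = luts[iy0[:, None], ix0[None, :], img]
    l01 = luts[iy0[:, None], ix1[None, :], img]
    l10 = luts[iy1[:, None], ix0[None, :], img]
    l11 = luts[iy1[:, None], ix1[None, :], img]

    wy_c = wy[:, None]
    wx_r = wx[None, :]
    out = ((1.0 - wy_c) * ((1.0 - wx_r) * l00 + wx_r * l01)
           + wy_c * ((1.0 - wx_r) * l10 + wx_r * l11))
    return np.rint(out).astype(np.uint8)
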