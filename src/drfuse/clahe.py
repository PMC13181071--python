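"""Contrast-limited adaptive histogram equalization (CLAHE) for 8-bit images.

The image is divided into a grid of tiles; each tile's histogram is clipped
at a limit (curbing noise over-amplification), re-normalized, and equalized
into a per-tile lookup table. Every output pixel blends the lookup tables
of its four nearest tile centers bilinearly, which removes visible tile
seams. Color images are enhanced on the BT.601 luminance channel only,
leaving chroma untouched.

The clip limit is expressed relative to the mean bin height (effective
per-tile limit = max(1, clip_limit · tile_area / n_bins)), so the same
number behaves consistently across tile sizes; 2.0 with an 8×8 grid is the
configuration used for fundus preprocessing throughout this package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from PIL import Image

from .errors import InvalidInputError

__all__ = [
    "ClaheParams",
    "clip_histogram",
    "equalize_map",
    "clahe_gray",
    "clahe_color",
    "resize_bilinear",
    "load_image",
    "save_image",
]

LUMA_WEIGHTS = (0.299, 0.587, 0.114)  # ITU-R BT.601


@dataclass(frozen=True)
class ClaheParams:
    clip_limit: float = 2.0
    tile_grid: tuple = (8, 8)
    n_bins: int = 256

    def __post_init__(self):
        if self.clip_limit <= 0:
            raise InvalidInputError("clip_limit must be positive")
        rows, cols = self.tile_grid
        if rows < 1 or cols < 1:
            raise InvalidInputError("tile grid counts must be >= 1")
        if self.n_bins < 1 or self.n_bins > 256:
            raise InvalidInputError("n_bins must lie in [1, 256]")


def _check_u8(img) -> np.ndarray:
    a = np.asarray(img)
    if a.size == 0:
        raise InvalidInputError("empty image")
    if np.issubdtype(a.dtype, np.floating):
        if np.any(a != np.round(a)):
            raise InvalidInputError("pixel values must be integral")
    a = a.astype(np.int64)
    if a.min() < 0 or a.max() > 255:
        raise InvalidInputError("pixel values must lie in [0, 255]")
    return a


def clip_histogram(hist, limit: float) -> np.ndarray:
    """Truncate bins above ``limit`` and redistribute the excess uniformly.

    One-pass redistribution: bins may marginally exceed the limit afterwards,
    but total mass is conserved exactly.
    """
    h = np.asarray(hist, dtype=float)
    if np.any(h < 0):
        raise InvalidInputError("histogram bins must be nonnegative")
    if limit <= 0:
        raise InvalidInputError("clip limit must be positive")
    excess = np.maximum(h - limit, 0.0).sum()
    return np.minimum(h, limit) + excess / h.size


def equalize_map(clipped_hist) -> np.ndarray:
    """Equalization lookup table: LUT(v) = round(255 · CDF(v)).

    Monotone non-decreasing; the last bin with mass maps to 255.
    """
    h = np.asarray(clipped_hist, dtype=float)
    if np.any(h < 0):
        raise InvalidInputError("histogram bins must be nonnegative")
    total = h.sum()
    if total <= 0:
        raise InvalidInputError("histogram has zero mass")
    cdf = np.cumsum(h) / total
    return np.clip(np.round(255.0 * cdf), 0, 255).astype(np.uint8)


def clahe_gray(img, params: ClaheParams = ClaheParams()) -> np.ndarray:
    """CLAHE on a grayscale 8-bit image.

    Steps: pad by edge replication to a multiple of the tile size; per tile
    compute the histogram, clip it at the effective limit, and build an
    equalization LUT; map each pixel through the bilinear blend of the four
    nearest tile-center LUTs (clamped at borders); crop back.
    """
    a = _check_u8(img)
    if a.ndim != 2:
        raise InvalidInputError("clahe_gray expects a 2-d grayscale image")
    H, W = a.shape
    rows, cols = params.tile_grid
    th = math.ceil(H / rows)
    tw = math.ceil(W / cols)
    padded = np.pad(a, ((0, rows * th - H), (0, cols * tw - W)), mode="edge")

    n_bins = params.n_bins
    # bin index per pixel (identity for 256 bins)
    bins = (padded * n_bins) // 256

    tile_area = th * tw
    limit = max(1.0, params.clip_limit * tile_area / n_bins)
    luts = np.empty((rows, cols, n_bins), dtype=np.float64)
    for r in range(rows):
        for c in range(cols):
            tile = bins[r * th : (r + 1) * th, c * tw : (c + 1) * tw]
            hist = np.bincount(tile.ravel(), minlength=n_bins).astype(float)
            luts[r, c] = equalize_map(clip_histogram(hist, limit))

    # fractional tile-center coordinates of every padded pixel, clamped
    fy = np.clip((np.arange(rows * th) + 0.5) / th - 0.5, 0, rows - 1)
    fx = np.clip((np.arange(cols * tw) + 0.5) / tw - 0.5, 0, cols - 1)
    y0 = np.floor(fy).astype(int)
    x0 = np.floor(fx).astype(int)
    y1 = np.minimum(y0 + 1, rows - 1)
    x1 = np.minimum(x0 + 1, cols - 1)
    wy = (fy - y0)[:, None]
    wx = (fx - x0)[None, :]

    Y0 = y0[:, None]
    Y1 = y1[:, None]
    X0 = x0[None, :]
    X1 = x1[None, :]
    out = (
        (1 - wy) * (1 - wx) * luts[Y0, X0, bins]
        + (1 - wy) * wx * luts[Y0, X1, bins]
        + wy * (1 - wx) * luts[Y1, X0, bins]
        + wy * wx * luts[Y1, X1, bins]
    )
    out = np.clip(np.round(out), 0, 255).astype(np.uint8)
    return out[:H, :W]


def clahe_color(img, params: ClaheParams = ClaheParams()) -> np.ndarray:
    """CLAHE on the luminance channel of an RGB image.

    The BT.601 luma plane is enhanced with :func:`clahe_gray`; the luma
    delta is added back to all three channels, which leaves the chroma
    components (channel differences) unchanged except where the final
    clip to [0, 255] saturates.
    """
    a = _check_u8(img)
    if a.ndim != 3 or a.shape[2] != 3:
        raise InvalidInputError("clahe_color expects an (H, W, 3) RGB image")
    wr, wg, wb = LUMA_WEIGHTS
    luma = wr * a[..., 0] + wg * a[..., 1] + wb * a[..., 2]
    y8 = np.clip(np.round(luma), 0, 255).astype(np.uint8)
    y_eq = clahe_gray(y8, params).astype(np.int64)
    delta = y_eq - y8.astype(np.int64)
    return np.clip(a + delta[..., None], 0, 255).astype(np.uint8)


def resize_bilinear(img, height: int, width: int) -> np.ndarray:
    """Bilinear resampling to an exact target size (224×224 for model input)."""
    if height < 1 or width < 1:
        raise InvalidInputError("target size must be positive")
    a = _check_u8(img).astype(np.uint8)
    if a.shape[:2] == (height, width):
        return a.copy()
    mode = "L" if a.ndim == 2 else "RGB"
    resized = Image.fromarray(a, mode=mode).resize((width, height), Image.BILINEAR)
    return np.asarray(resized)


def load_image(path) -> np.ndarray:
    """Load a PNG (or any Pillow-readable raster) as 8-bit gray or RGB array."""
    with Image.open(path) as im:
        if im.mode in ("L", "RGB"):
            return np.asarray(im)
        if im.mode in ("I", "F", "I;16"):
            raise InvalidInputError("only 8-bit images are supported")
        return np.asarray(im.convert("RGB"))


def save_image(path, img) -> None:
    a = _check_u8(img).astype(np.uint8)
    mode = "L" if a.ndim == 2 else "RGB"
    Image.fromarray(a, mode=mode).save(path)
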