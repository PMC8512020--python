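"""Channel handling, CLAHE contrast enhancement and retina-mask construction.

A fundus photograph is a 24-bit RGB image of the back of the eye: a bright,
roughly circular retina disc on a black camera surround, with the vessel tree
darkest (highest local contrast) in the green channel.  Everything downstream
of this module works on a single 8-bit plane, so the entry points here reduce
the colour image to one channel, boost local contrast with CLAHE, and build
the binary field-of-view mask used later to delete the spurious rim edge.

Images are plain numpy arrays: colour images are ``(H, W, 3) uint8``, grey
images ``(H, W) uint8`` (row-major, origin top-left) and masks ``(H, W) bool``.
"""

from __future__ import annotations

from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

__all__ = [
    "DimensionError",
    "ParameterError",
    "ClaheSpec",
    "read_color_image",
    "read_mask",
    "write_gray_image",
    "write_mask",
    "write_color_image",
    "extract_green",
    "to_grayscale",
    "clahe",
    "compute_retina_mask",
    "shrink_mask",
]

# BT.601 luma weights; they sum to exactly 1.0 so constant images are fixed
# points of the grayscale conversion.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

DEFAULT_BG_THRESHOLD = 10
DEFAULT_SHRINK_RADIUS = 5


class DimensionError(ValueError):
    """Image planes or maps whose shapes do not line up."""


class ParameterError(ValueError):
    """A parameter outside its documented range."""


@dataclass(frozen=True)
class ClaheSpec:
    """CLAHE settings: histogram clip factor and square tile side in pixels.

    ``clip_limit`` is the usual dimensionless factor relative to the uniform
    histogram height (a bin may hold at most ``clip_limit * tile_area / 256``
    counts); ``tile_size`` is the side of the square contextual region.
    """

    clip_limit: float = 2.0
    tile_size: int = 15

    def __post_init__(self) -> None:
        if self.clip_limit <= 0:
            raise ParameterError(f"clip_limit must be > 0, got {self.clip_limit}")
        if self.tile_size < 3:
            raise ParameterError(f"tile_size must be >= 3, got {self.tile_size}")


# ---------------------------------------------------------------------------
# validation helpers
# ---------------------------------------------------------------------------

def as_color(img: np.ndarray) -> np.ndarray:
    """Validate an RGB image, dropping an alpha channel if present."""
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise DimensionError(
            f"expected an (H, W, 3) colour image, got shape {arr.shape}"
        )
    if arr.shape[2] == 4:  # alpha is dropped on read
        arr = arr[:, :, :3]
    return np.ascontiguousarray(arr.astype(np.uint8, copy=False))


def as_gray(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise DimensionError(f"expected an (H, W) grey image, got shape {arr.shape}")
    return arr.astype(np.uint8, copy=False)


def round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer with .5 going up, clip to 8-bit range."""
    return np.clip(np.floor(np.asarray(x, dtype=np.float64) + 0.5), 0, 255).astype(
        np.uint8
    )


# ---------------------------------------------------------------------------
# file I/O (PNG / TIFF / JPEG / GIF; always 8-bit)
# ---------------------------------------------------------------------------

def read_color_image(path) -> np.ndarray:
    """Read an RGB fundus image; greyscale files are replicated to 3 planes."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return as_color(arr)


def read_mask(path) -> np.ndarray:
    """Read a binary map (e.g. a DRIVE ground-truth GIF) as a bool array."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return np.asarray(arr) > 127


def write_gray_image(path, img: np.ndarray) -> None:
    iio.imwrite(path, as_gray(img))


def write_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def write_color_image(path, img: np.ndarray) -> None:
    iio.imwrite(path, as_color(img))


# ---------------------------------------------------------------------------
# channel reduction
# ---------------------------------------------------------------------------

def extract_green(img: np.ndarray) -> np.ndarray:
    """Return the green plane of an RGB image unchanged (no rescaling).

    The green channel carries the best vessel/background contrast in fundus
    photography, so it is the working plane of the whole pipeline.
    """
    return as_color(img)[:, :, 1].copy()


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """BT.601 luminance (0.299 R + 0.587 G + 0.114 B), rounded half-up."""
    arr = as_color(img).astype(np.float64)
    return round_half_up(arr @ _LUMA_WEIGHTS)


# ---------------------------------------------------------------------------
# CLAHE
# ---------------------------------------------------------------------------

def clahe(img: np.ndarray, spec: ClaheSpec = ClaheSpec()) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on an 8-bit plane.

    The image is covered by ``tile_size`` x ``tile_size`` tiles (padded by
    reflection to a whole number of tiles).  Each tile's 256-bin histogram is
    clipped at ``clip_limit * tile_area / 256`` counts, the clipped excess is
    redistributed uniformly over all bins in a single pass, and the tile's
    mapping is the rescaled CDF.  A pixel's output value bilinearly blends
    the mappings of the four nearest tile centres, which keeps the result
    continuous across tile borders; pixels beyond the outermost tile centres
    fall back to the nearest tile's mapping.

    A constant image maps to a constant image, and for a very large clip
    limit each tile's mapping tends to plain histogram equalization.
    """
    img = as_gray(img)
    h, w = img.shape
    ts = int(spec.tile_size)
    if ts > min(h, w):
        raise ParameterError(
            f"tile_size {ts} exceeds image extent {min(h, w)}"
        )

    nty = -(-h // ts)
    ntx = -(-w // ts)
    padded = np.pad(img, ((0, nty * ts - h), (0, ntx * ts - w)), mode="symmetric")
    area = ts * ts
    clip = max(1.0, spec.clip_limit * area / 256.0)

    tiles = (
        padded.reshape(nty, ts, ntx, ts).transpose(0, 2, 1, 3).reshape(nty, ntx, area)
    )
    luts = np.empty((nty, ntx, 256), dtype=np.float64)
    for i in range(nty):
        for j in range(ntx):
            hist = np.bincount(tiles[i, j], minlength=256).astype(np.float64)
            excess = np.sum(np.maximum(hist - clip, 0.0))
            hist = np.minimum(hist, clip) + excess / 256.0
            cdf = np.cumsum(hist)
            luts[i, j] = np.floor(cdf * (255.0 / area) + 0.5)

    # bilinear weights relative to tile centres
    def _axis(n_pix: int, n_tiles: int):
        g = (np.arange(n_pix) + 0.5) / ts - 0.5
        f = np.floor(g)
        i0 = np.clip(f.astype(int), 0, n_tiles - 1)
        i1 = np.clip(f.astype(int) + 1, 0, n_tiles - 1)
        return i0, i1, g - f

    y0, y1, wy = _axis(h, nty)
    x0, x1, wx = _axis(w, ntx)
    Y0, Y1, WY = y0[:, None], y1[:, None], wy[:, None]
    X0, X1, WX = x0[None, :], x1[None, :], wx[None, :]

    top = (1.0 - WX) * luts[Y0, X0, img] + WX * luts[Y0, X1, img]
    bot = (1.0 - WX) * luts[Y1, X0, img] + WX * luts[Y1, X1, img]
    return round_half_up((1.0 - WY) * top + WY * bot)


# ---------------------------------------------------------------------------
# retina field-of-view mask
# ---------------------------------------------------------------------------

def compute_retina_mask(
    green: np.ndarray, bg_threshold: int = DEFAULT_BG_THRESHOLD
) -> np.ndarray:
    """Threshold the green plane to separate the retina disc from the black
    camera surround.  Strictly greater-than: a pixel exactly at the threshold
    is background.
    """
    if not 0 <= bg_threshold <= 255:
        raise ParameterError(f"bg_threshold must be in [0, 255], got {bg_threshold}")
    return as_gray(green) > bg_threshold


def shrink_mask(mask: np.ndarray, radius: int = DEFAULT_SHRINK_RADIUS) -> np.ndarray:
    """Erode the foreground by a square structuring element of side 2r+1.

    Shrinking the retina mask slightly pulls it inside the bright circular
    field-of-view rim, so that masking the edge map removes the rim edge.
    """
    if radius < 0:
        raise ParameterError(f"radius must be >= 0, got {radius}")
    mask = np.asarray(mask, dtype=bool)
    if radius == 0:
        return mask.copy()
    se = np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)
    return ndimage.binary_erosion(mask, structure=se, border_value=0)
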