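"""The modified Canny detector for retinal vessel edges.

Pipeline (in order): green-channel extraction -> CLAHE -> Gaussian smoothing
-> Sobel gradients -> non-maximum suppression -> double thresholding ->
hysteresis edge tracking -> retinal outline removal.  Every stage is exposed
as its own function so each can be tested against an independent oracle;
:func:`detect` is the full composition.

Gradient magnitudes are kept in floating point throughout; only smoothing
re-quantizes to 8-bit, mirroring the behaviour of an 8-bit image pipeline.
All convolutions use reflect-101 ("mirror") border handling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage

from .preprocess import (
    DEFAULT_BG_THRESHOLD,
    DEFAULT_SHRINK_RADIUS,
    ClaheSpec,
    DimensionError,
    ParameterError,
    as_gray,
    clahe,
    compute_retina_mask,
    extract_green,
    round_half_up,
    shrink_mask,
    to_grayscale,
)

__all__ = [
    "GaussianSpec",
    "DetectorParams",
    "GradientField",
    "IRRELEVANT",
    "WEAK",
    "STRONG",
    "gaussian_kernel",
    "smooth",
    "gradients",
    "nonmax_suppress",
    "double_threshold",
    "hysteresis",
    "remove_outline",
    "pipeline_front",
    "detect_from_nms",
    "detect",
    "load_params",
    "save_params",
]

log = logging.getLogger(__name__)

# pixel classes assigned by double thresholding
IRRELEVANT, WEAK, STRONG = 0, 1, 2

_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
_SOBEL_Y = np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], dtype=np.float64)

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class GaussianSpec:
    """Square Gaussian smoothing kernel: odd side ``size`` and spread ``sigma``
    (the same standard deviation in x and y)."""

    size: int = 5
    sigma: float = 1.4

    def __post_init__(self) -> None:
        if self.size < 1 or self.size % 2 == 0:
            raise ParameterError(f"kernel size must be odd and >= 1, got {self.size}")
        if self.sigma <= 0:
            raise ParameterError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class DetectorParams:
    """Full parameter set of the detector.

    Defaults are the tool's toolbar defaults: low threshold 30 and high
    threshold 105 on raw Sobel magnitudes, a 5x5 Gaussian with sigma 1.4, and
    CLAHE at clip limit 2.0.  Unless a :class:`ClaheSpec` is given explicitly,
    the CLAHE tile side is coupled to triple the Gaussian kernel size
    (5x5 kernel -> 15x15 tiles): the tile must stay large relative to the
    noise scale the Gaussian suppresses.
    """

    low_threshold: float = 30.0
    high_threshold: float = 105.0
    gaussian: GaussianSpec = field(default_factory=GaussianSpec)
    clahe: ClaheSpec | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.low_threshold <= self.high_threshold:
            raise ParameterError(
                f"need 0 <= low <= high, got low={self.low_threshold} "
                f"high={self.high_threshold}"
            )
        if self.clahe is None:
            object.__setattr__(
                self, "clahe", ClaheSpec(tile_size=3 * self.gaussian.size)
            )

    @classmethod
    def create(
        cls,
        low: float = 30.0,
        high: float = 105.0,
        kernel: int = 5,
        sigma: float = 1.4,
        clip_limit: float = 2.0,
        tile: int | None = None,
    ) -> "DetectorParams":
        """Build params from the flat toolbar values; ``tile`` defaults to
        3 x ``kernel``."""
        spec = ClaheSpec(clip_limit, tile if tile is not None else 3 * kernel)
        return cls(low, high, GaussianSpec(kernel, sigma), spec)

    def to_dict(self) -> dict:
        return {
            "low": float(self.low_threshold),
            "high": float(self.high_threshold),
            "kernel": int(self.gaussian.size),
            "sigma": float(self.gaussian.sigma),
            "clip_limit": float(self.clahe.clip_limit),
            "tile": int(self.clahe.tile_size),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorParams":
        base = cls.create()
        merged = base.to_dict() | dict(d)
        return cls.create(
            low=merged["low"],
            high=merged["high"],
            kernel=merged["kernel"],
            sigma=merged["sigma"],
            clip_limit=merged["clip_limit"],
            tile=merged["tile"] if "tile" in d else None,
        )


def load_params(path) -> DetectorParams:
    """Load detector parameters from a YAML config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return DetectorParams.from_dict(data)


def save_params(path, params: DetectorParams) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


@dataclass
class GradientField:
    """Per-pixel Sobel responses gx, gy with polar magnitude and angle.

    ``magnitude = sqrt(gx^2 + gy^2)`` and ``angle = atan2(gy, gx)`` in
    radians; gy is the response of the vertical (row-direction) Sobel kernel.
    """

    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray
    angle: np.ndarray


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def gaussian_kernel(spec: GaussianSpec = GaussianSpec()) -> np.ndarray:
    """Normalized isotropic Gaussian kernel exp(-(x^2+y^2)/(2 sigma^2)) on the
    centred integer grid, scaled to sum to 1."""
    half = spec.size // 2
    ax = np.arange(-half, half + 1, dtype=np.float64)
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx * xx + yy * yy) / (2.0 * spec.sigma * spec.sigma))
    return k / k.sum()


def smooth(img: np.ndarray, spec: GaussianSpec = GaussianSpec()) -> np.ndarray:
    """Gaussian-filter an 8-bit plane (reflected borders, rounded back to
    8-bit)."""
    img = as_gray(img)
    if min(img.shape) < spec.size:
        raise ParameterError(
            f"image {img.shape} smaller than kernel size {spec.size}"
        )
    out = ndimage.correlate(
        img.astype(np.float64), gaussian_kernel(spec), mode="mirror"
    )
    return round_half_up(out)


def gradients(img: np.ndarray) -> GradientField:
    """3x3 Sobel responses and their polar form."""
    arr = as_gray(img).astype(np.float64)
    gx = ndimage.correlate(arr, _SOBEL_X, mode="mirror")
    gy = ndimage.correlate(arr, _SOBEL_Y, mode="mirror")
    return GradientField(gx, gy, np.hypot(gx, gy), np.arctan2(gy, gx))


def nonmax_suppress(fld: GradientField) -> np.ndarray:
    """Thin gradient ridges to candidate edge pixels.

    The gradient angle is quantized (modulo 180 degrees) to one of four edge
    normals - horizontal, +45, vertical, -45 - and a pixel keeps its
    magnitude only if it is not lower than either neighbour along that
    normal (ties survive, so plateau ridges are preserved).  The outermost
    1-pixel frame is always suppressed.
    """
    mag = np.asarray(fld.magnitude, dtype=np.float64)
    h, w = mag.shape
    deg = np.rad2deg(fld.angle) % 180.0
    sector = (((deg + 22.5) // 45.0).astype(int)) % 4

    padded = np.pad(mag, 1, constant_values=-np.inf)

    def shifted(dr: int, dc: int) -> np.ndarray:
        return padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]

    n1 = np.empty_like(mag)
    n2 = np.empty_like(mag)
    # neighbour offsets (drow, dcol) along the quantized gradient direction
    for s, (dr, dc) in enumerate([(0, 1), (1, 1), (1, 0), (1, -1)]):
        sel = sector == s
        n1[sel] = shifted(dr, dc)[sel]
        n2[sel] = shifted(-dr, -dc)[sel]

    out = np.where((mag >= n1) & (mag >= n2), mag, 0.0)
    out[0, :] = out[-1, :] = 0.0
    out[:, 0] = out[:, -1] = 0.0
    return out


def double_threshold(nms: np.ndarray, low: float, high: float) -> np.ndarray:
    """Classify suppressed magnitudes into irrelevant / weak / strong.

    Strictly greater-than comparisons: value > high is strong, low < value
    <= high is weak, value <= low is irrelevant.
    """
    if not 0 <= low <= high:
        raise ParameterError(f"need 0 <= low <= high, got low={low} high={high}")
    nms = np.asarray(nms, dtype=np.float64)
    classes = np.zeros(nms.shape, dtype=np.uint8)
    classes[nms > low] = WEAK
    classes[nms > high] = STRONG
    return classes


def hysteresis(classes: np.ndarray) -> np.ndarray:
    """Edge tracking: keep strong pixels plus weak pixels 8-connected to a
    strong pixel, transitively through other weak pixels."""
    classes = np.asarray(classes)
    present = classes > IRRELEVANT
    if not present.any():
        return np.zeros(classes.shape, dtype=bool)
    labels, n = ndimage.label(present, structure=_EIGHT)
    strong_labels = np.unique(labels[classes == STRONG])
    return np.isin(labels, strong_labels[strong_labels > 0])


def remove_outline(edges: np.ndarray, retina_mask: np.ndarray) -> np.ndarray:
    """AND the edge map with the (shrunken) retina mask, deleting the
    circular field-of-view rim and anything on the camera surround."""
    edges = np.asarray(edges, dtype=bool)
    retina_mask = np.asarray(retina_mask, dtype=bool)
    if edges.shape != retina_mask.shape:
        raise DimensionError(
            f"edge map {edges.shape} vs mask {retina_mask.shape}"
        )
    return edges & retina_mask


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def pipeline_front(
    img: np.ndarray,
    params: DetectorParams,
    *,
    channel: str = "green",
    apply_clahe: bool = True,
    bg_threshold: int = DEFAULT_BG_THRESHOLD,
    shrink_radius: int = DEFAULT_SHRINK_RADIUS,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the threshold-independent front of the pipeline.

    Returns the non-maximum-suppressed magnitude grid and the shrunken retina
    mask.  The thresholding stages (:func:`detect_from_nms`) are the only
    part that depends on ``low``/``high``, so callers sweeping thresholds can
    reuse this result; the composition is identical to :func:`detect`.
    """
    if channel == "green":
        plane = extract_green(img)
    elif channel == "gray":
        plane = to_grayscale(img)
    else:
        raise ParameterError(f"unknown channel {channel!r}")
    log.info("channel=%s -> 8-bit plane %s", channel, plane.shape)

    mask = shrink_mask(compute_retina_mask(plane, bg_threshold), shrink_radius)
    log.info("retina mask: bg_threshold=%d shrink_radius=%d", bg_threshold, shrink_radius)

    if apply_clahe:
        plane = clahe(plane, params.clahe)
        log.info(
            "clahe: clip_limit=%.2f tile=%d",
            params.clahe.clip_limit,
            params.clahe.tile_size,
        )
    sm = smooth(plane, params.gaussian)
    log.info("gaussian: size=%d sigma=%.2f", params.gaussian.size, params.gaussian.sigma)
    nms = nonmax_suppress(gradients(sm))
    log.info("sobel gradients + non-maximum suppression done")
    return nms, mask


def detect_from_nms(
    nms: np.ndarray, retina_mask: np.ndarray, low: float, high: float
) -> np.ndarray:
    """Thresholding tail of the pipeline: double threshold, hysteresis,
    outline removal."""
    edges = hysteresis(double_threshold(nms, low, high))
    return remove_outline(edges, retina_mask)


def detect(
    img: np.ndarray,
    params: DetectorParams = DetectorParams(),
    *,
    channel: str = "green",
    apply_clahe: bool = True,
    bg_threshold: int = DEFAULT_BG_THRESHOLD,
    shrink_radius: int = DEFAULT_SHRINK_RADIUS,
) -> np.ndarray:
    """Full modified-Canny vessel edge detection on an RGB fundus image.

    ``channel`` selects the working plane ("green", the default and the
    method's choice, or "gray" for the luminance baseline) and
    ``apply_clahe`` can disable contrast enhancement; both exist for
    preprocessing comparisons.  Deterministic: identical input and params
    give a bit-identical edge map.
    """
    nms, mask = pipeline_front(
        img,
        params,
        channel=channel,
        apply_clahe=apply_clahe,
        bg_threshold=bg_threshold,
        shrink_radius=shrink_radius,
    )
    edges = detect_from_nms(nms, mask, params.low_threshold, params.high_threshold)
    log.info(
        "thresholds low=%.1f high=%.1f -> %d edge pixels",
        params.low_threshold,
        params.high_threshold,
        int(edges.sum()),
    )
    return edges
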