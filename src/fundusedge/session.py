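"""Headless engine behind interactive per-region vessel segmentation.

The GUI workflow - press a colour key, drag the cursor along a vessel, and
edges detected with the current toolbar parameters appear in that colour
around the cursor path - is reproduced here as a scriptable API.  A
:class:`Stroke` records one cursor drag (path, brush radius, colour, mode and
a snapshot of the detector parameters); a :class:`Session` accumulates
strokes into per-colour edge layers over one source image, so different
threshold settings can be applied to different regions of the same image.

The GUI's single-key vocabulary is kept as the stroke-log file format:
``b/g/p/y`` select the layer colour, ``w`` erases, ``m``/``a`` are manual and
automatic modes.  One stroke per line::

    <mode> <color> <radius> low=.. high=.. kernel=.. sigma=.. clip=.. tile=.. : r,c r,c ...

where ``<mode>`` is ``a`` (detect within the brush region), ``m`` (draw the
path itself as edges) or ``w`` (erase the brush region from every layer), and
the path is a whitespace-separated list of ``row,col`` pixel coordinates.
Blank lines and lines starting with ``#`` are ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .canny import DetectorParams, detect
from .preprocess import (
    DEFAULT_BG_THRESHOLD,
    DEFAULT_SHRINK_RADIUS,
    ParameterError,
    as_color,
    compute_retina_mask,
    extract_green,
    shrink_mask,
    write_color_image,
    write_mask,
)

__all__ = [
    "COLOR_IDS",
    "COLOR_RGB",
    "DEFAULT_BRUSH_RADIUS",
    "Stroke",
    "Session",
    "StrokeLogError",
    "stroke_region",
    "format_stroke",
    "parse_stroke",
    "save_stroke_log",
    "load_stroke_log",
    "export_layers",
]

log = logging.getLogger(__name__)

COLOR_IDS = ("blue", "green", "purple", "yellow")
COLOR_RGB = {
    "blue": (0, 0, 255),
    "green": (0, 255, 0),
    "purple": (160, 32, 240),
    "yellow": (255, 255, 0),
}
_COLOR_KEY = {"blue": "b", "green": "g", "purple": "p", "yellow": "y"}
_KEY_COLOR = {v: k for k, v in _COLOR_KEY.items()}
_MODE_KEY = {"auto": "a", "manual": "m", "erase": "w"}
_KEY_MODE = {v: k for k, v in _MODE_KEY.items()}

DEFAULT_BRUSH_RADIUS = 15


class StrokeLogError(ValueError):
    """Malformed stroke-log line."""


@dataclass(frozen=True)
class Stroke:
    """One cursor drag: an ordered pixel path with brush radius, layer
    colour, mode and the detector parameters in force at the time."""

    path: tuple[tuple[int, int], ...]
    radius: int = DEFAULT_BRUSH_RADIUS
    color: str = "blue"
    mode: str = "auto"
    params: DetectorParams = field(default_factory=DetectorParams)

    def __post_init__(self) -> None:
        if len(self.path) == 0:
            raise ParameterError("stroke path must be nonempty")
        if self.radius < 1:
            raise ParameterError(f"radius must be >= 1, got {self.radius}")
        if self.color not in COLOR_IDS:
            raise ParameterError(f"unknown color {self.color!r}")
        if self.mode not in _MODE_KEY:
            raise ParameterError(f"unknown mode {self.mode!r}")
        object.__setattr__(
            self, "path", tuple((int(r), int(c)) for r, c in self.path)
        )


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _disk(radius: int) -> np.ndarray:
    ax = np.arange(-radius, radius + 1)
    xx, yy = np.meshgrid(ax, ax)
    return xx * xx + yy * yy <= radius * radius


def _bresenham(p0: tuple[int, int], p1: tuple[int, int]):
    """Integer line from p0 to p1 inclusive."""
    r0, c0 = p0
    r1, c1 = p1
    dr, dc = abs(r1 - r0), abs(c1 - c0)
    sr = 1 if r1 >= r0 else -1
    sc = 1 if c1 >= c0 else -1
    err = dr - dc
    r, c = r0, c0
    while True:
        yield r, c
        if (r, c) == (r1, c1):
            return
        e2 = 2 * err
        if e2 > -dc:
            err -= dc
            r += sr
        if e2 < dr:
            err += dr
            c += sc


def _path_mask(stroke: Stroke, shape: tuple[int, int]) -> np.ndarray:
    """1-pixel polyline through the stroke path, clipped to bounds."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    pts = stroke.path
    for a, b in zip(pts, pts[1:] or pts):
        for r, c in _bresenham(a, b):
            if 0 <= r < h and 0 <= c < w:
                mask[r, c] = True
    return mask


def stroke_region(stroke: Stroke, shape: tuple[int, int]) -> np.ndarray:
    """Brush footprint: union of Euclidean discs of the stroke radius swept
    along the path (consecutive points joined by Bresenham segments);
    out-of-bounds parts are clipped."""
    return ndimage.binary_dilation(
        _path_mask(stroke, shape), structure=_disk(stroke.radius)
    )


# ---------------------------------------------------------------------------
# session
# ---------------------------------------------------------------------------

class Session:
    """Stateful segmentation session over one fundus image.

    Layers are independent binary edge maps, one per colour, always confined
    to the shrunken retina mask.  Full-image detection results are cached per
    unique parameter snapshot so repeated strokes at the same toolbar setting
    cost one detector run.  An owner map records which colour painted each
    pixel last, so composites resolve overlaps latest-stroke-wins.
    """

    def __init__(
        self,
        source: np.ndarray,
        *,
        bg_threshold: int = DEFAULT_BG_THRESHOLD,
        shrink_radius: int = DEFAULT_SHRINK_RADIUS,
    ) -> None:
        self.source = as_color(source)
        self.bg_threshold = bg_threshold
        self.shrink_radius = shrink_radius
        shape = self.source.shape[:2]
        self.retina_mask = shrink_mask(
            compute_retina_mask(extract_green(self.source), bg_threshold),
            shrink_radius,
        )
        self.layers: dict[str, np.ndarray] = {
            c: np.zeros(shape, dtype=bool) for c in COLOR_IDS
        }
        self.stroke_log: list[Stroke] = []
        self._owner = np.zeros(shape, dtype=np.uint8)  # 0 = none, 1+idx = colour
        self._edge_cache: dict[DetectorParams, np.ndarray] = {}

    @property
    def shape(self) -> tuple[int, int]:
        return self.source.shape[:2]

    def full_edges(self, params: DetectorParams) -> np.ndarray:
        """Whole-image detection at the given parameters (cached)."""
        if params not in self._edge_cache:
            self._edge_cache[params] = detect(
                self.source,
                params,
                bg_threshold=self.bg_threshold,
                shrink_radius=self.shrink_radius,
            )
        return self._edge_cache[params]

    def apply_stroke(self, stroke: Stroke) -> "Session":
        """Apply one stroke and return self.

        auto: edges detected at the stroke's params, restricted to the brush
        region, are added to the stroke's colour layer.  manual: the 1-pixel
        path itself is added.  erase: the brush region is cleared from every
        layer.  Pixels outside the brush region are never modified.
        """
        region = stroke_region(stroke, self.shape)
        idx = COLOR_IDS.index(stroke.color) + 1
        if stroke.mode == "auto":
            added = self.full_edges(stroke.params) & region
            self.layers[stroke.color] |= added
            self._owner[added] = idx
        elif stroke.mode == "manual":
            added = _path_mask(stroke, self.shape) & self.retina_mask
            self.layers[stroke.color] |= added
            self._owner[added] = idx
        else:  # erase
            for color in COLOR_IDS:
                self.layers[color] &= ~region
            self._owner[region] = 0
        self.stroke_log.append(stroke)
        log.info(
            "stroke %d: mode=%s color=%s radius=%d points=%d",
            len(self.stroke_log),
            stroke.mode,
            stroke.color,
            stroke.radius,
            len(stroke.path),
        )
        return self

    def merged(self) -> np.ndarray:
        """Union of all colour layers."""
        out = np.zeros(self.shape, dtype=bool)
        for layer in self.layers.values():
            out |= layer
        return out

    def composite(self) -> np.ndarray:
        """Source image with each layer painted its colour; where layers
        overlap the most recent stroke's colour wins."""
        out = self.source.copy()
        for i, color in enumerate(COLOR_IDS):
            sel = self.layers[color] & (self._owner == i + 1)
            out[sel] = COLOR_RGB[color]
        return out

    @classmethod
    def replay(cls, source: np.ndarray, strokes, **kwargs) -> "Session":
        """Build a fresh session and apply the strokes in order; replaying a
        session's own stroke_log reproduces its layers exactly."""
        sess = cls(source, **kwargs)
        for stroke in strokes:
            sess.apply_stroke(stroke)
        return sess


# ---------------------------------------------------------------------------
# stroke-log text format
# ---------------------------------------------------------------------------

def format_stroke(stroke: Stroke) -> str:
    p = stroke.params.to_dict()
    head = (
        f"{_MODE_KEY[stroke.mode]} {_COLOR_KEY[stroke.color]} {stroke.radius} "
        f"low={p['low']:g} high={p['high']:g} kernel={p['kernel']} "
        f"sigma={p['sigma']:g} clip={p['clip_limit']:g} tile={p['tile']}"
    )
    coords = " ".join(f"{r},{c}" for r, c in stroke.path)
    return f"{head} : {coords}"


def parse_stroke(line: str) -> Stroke:
    try:
        head, _, tail = line.partition(":")
        tokens = head.split()
        if len(tokens) < 3:
            raise ValueError("expected '<mode> <color> <radius> ... : path'")
        mode = _KEY_MODE[tokens[0]]
        color = _KEY_COLOR[tokens[1]]
        radius = int(tokens[2])
        kv = dict(t.split("=", 1) for t in tokens[3:])
        params = DetectorParams.create(
            low=float(kv.get("low", 30)),
            high=float(kv.get("high", 105)),
            kernel=int(kv.get("kernel", 5)),
            sigma=float(kv.get("sigma", 1.4)),
            clip_limit=float(kv.get("clip", 2.0)),
            tile=int(kv["tile"]) if "tile" in kv else None,
        )
        path = tuple(
            (int(r), int(c))
            for r, c in (pt.split(",", 1) for pt in tail.split())
        )
        return Stroke(path=path, radius=radius, color=color, mode=mode, params=params)
    except StrokeLogError:
        raise
    except (KeyError, ValueError, ParameterError) as exc:
        raise StrokeLogError(f"malformed stroke line: {exc}") from exc


def save_stroke_log(path, strokes) -> None:
    with open(path, "w") as fh:
        for stroke in strokes:
            fh.write(format_stroke(stroke) + "\n")


def load_stroke_log(path) -> list[Stroke]:
    """Parse a stroke-log file; errors cite the 1-based line number."""
    strokes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                strokes.append(parse_stroke(line))
            except StrokeLogError as exc:
                raise StrokeLogError(f"line {lineno}: {exc}") from exc
    return strokes


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_layers(session: Session, outdir, stem: str = "segmented_img") -> dict:
    """Write per-colour edge maps, the merged map and the composite.

    The composite goes out both as ``<stem>.jpg`` (the tool's historical
    output name) and ``<stem>.png`` (lossless; byte-identical on re-export).
    Returns a dict of the written paths.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for color in COLOR_IDS:
        paths[color] = outdir / f"layer_{color}.png"
        write_mask(paths[color], session.layers[color])
    paths["union"] = outdir / "layer_union.png"
    write_mask(paths["union"], session.merged())
    comp = session.composite()
    paths["composite_jpg"] = outdir / f"{stem}.jpg"
    paths["composite_png"] = outdir / f"{stem}.png"
    write_color_image(paths["composite_jpg"], comp)
    write_color_image(paths["composite_png"], comp)
    return paths
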