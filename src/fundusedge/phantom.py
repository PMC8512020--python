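"""Synthetic fundus phantom generator with known vessel-boundary truth.

A phantom emulates the gross structure of a fundus photograph: a black
camera surround, a bright circular retina disc, and dark curvilinear vessels
of varying width and contrast inside the disc, plus additive Gaussian pixel
noise.  The colour composition concentrates the vessel structure in the
green channel (red near-saturated and flat, blue low), so green-channel
extraction genuinely outperforms a luminance conversion on these images,
as it does on real fundus photographs.

Vessel centrelines are cubic-spline-smoothed random walks with bounded
per-step curvature, growing outward from near the disc centre, optionally
with a single thinner branch.  Everything is driven by one integer seed:
the same spec always yields bit-identical images and truth maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .pfom import mask_boundary
from .preprocess import ParameterError, write_color_image, write_mask

__all__ = ["PhantomSpec", "PhantomTruth", "generate", "two_vessel_phantom", "save_phantom"]

# margin (px) by which vessels stay inside the disc, so that the boundary
# truth never touches the field-of-view rim
_DISC_MARGIN = 3


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic fundus image.

    Defaults emulate a small fundus scene at roughly one third of DRIVE
    resolution: a 192 px field with an 80 px retina disc, six vessels 1-4 px
    wide whose green-channel contrast spans 12-60 grey levels (vessel trees
    are dominated by thin vessels near the detection limit), and sigma = 6
    additive Gaussian noise.  ``red_texture_sigma`` optionally adds
    band-limited choroidal-style background texture to the red channel (off
    by default: the baseline composition keeps red and blue flat, with all
    vascular structure in the green plane).  Explicit per-vessel
    ``contrasts`` / ``widths`` override the sampled ranges.
    """

    seed: int = 0
    size: int = 192
    disc_radius: int = 80
    disc_intensity: tuple[int, int, int] = (190, 120, 35)
    background_intensity: tuple[int, int, int] = (0, 0, 0)
    n_vessels: int = 6
    vessel_width_range: tuple[int, int] = (1, 4)
    vessel_contrast_range: tuple[float, float] = (12.0, 60.0)
    noise_sigma: float = 6.0
    red_texture_sigma: float = 0.0
    red_texture_scale: float = 3.0
    contrasts: tuple[float, ...] | None = None
    widths: tuple[int, ...] | None = None
    branch_prob: float = 0.3

    def __post_init__(self) -> None:
        if self.disc_radius >= self.size / 2:
            raise ParameterError("disc_radius must be < size/2")
        if self.vessel_width_range[0] < 1:
            raise ParameterError("vessel widths must be >= 1")
        if self.vessel_contrast_range[0] < 1:
            raise ParameterError("vessel contrasts must be >= 1")
        if max(self.vessel_width_range) >= self.disc_radius:
            raise ParameterError("vessel wider than the disc is infeasible")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom image."""

    vessel_region_mask: np.ndarray
    vessel_boundary_map: np.ndarray
    retina_disc_mask: np.ndarray
    vessel_masks: list[np.ndarray] = field(default_factory=list)
    vessel_contrasts: list[float] = field(default_factory=list)
    vessel_widths: list[int] = field(default_factory=list)
    centerlines: list[np.ndarray] = field(default_factory=list)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _disc_mask(size: int, radius: int) -> np.ndarray:
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius * radius


def _disk_se(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    if r == 0:
        return np.ones((1, 1), dtype=bool)
    ax = np.arange(-r, r + 1)
    xx, yy = np.meshgrid(ax, ax)
    return xx * xx + yy * yy <= radius * radius


def _spline_points(waypoints: np.ndarray, samples_per_step: int = 16) -> np.ndarray:
    """Cubic-spline smooth a coarse (n, 2) waypoint walk and sample densely."""
    n = len(waypoints)
    if n < 3:
        t = np.linspace(0, 1, 8 * max(n, 2))
        return np.stack(
            [
                np.interp(t, np.linspace(0, 1, n), waypoints[:, 0]),
                np.interp(t, np.linspace(0, 1, n), waypoints[:, 1]),
            ],
            axis=1,
        )
    cs = CubicSpline(np.arange(n), waypoints, axis=0)
    t = np.linspace(0, n - 1, samples_per_step * (n - 1) + 1)
    return cs(t)


def _random_walk(
    rng: np.random.Generator,
    start: np.ndarray,
    heading: float,
    max_radius: float,
    center: float,
    step: float = 7.0,
    max_turn: float = 0.35,
) -> np.ndarray:
    """Coarse outward random walk with bounded per-step curvature."""
    pts = [start.astype(np.float64)]
    pos = start.astype(np.float64)
    for _ in range(200):
        heading += float(np.clip(rng.normal(0.0, 0.25), -max_turn, max_turn))
        pos = pos + step * np.array([np.sin(heading), np.cos(heading)])
        pts.append(pos.copy())
        if np.hypot(pos[0] - center, pos[1] - center) >= max_radius:
            break
    while len(pts) < 4:  # degenerate short walk: extend straight
        pos = pos + step * np.array([np.sin(heading), np.cos(heading)])
        pts.append(pos.copy())
    return np.array(pts)


def _rasterize_centerline(points: np.ndarray, size: int) -> np.ndarray:
    mask = np.zeros((size, size), dtype=bool)
    rr = np.round(points[:, 0]).astype(int)
    cc = np.round(points[:, 1]).astype(int)
    ok = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
    mask[rr[ok], cc[ok]] = True
    return mask


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def _compose(
    spec: PhantomSpec,
    centerlines: list[np.ndarray],
    widths: list[int],
    contrasts: list[float],
    rng: np.random.Generator,
) -> tuple[np.ndarray, PhantomTruth]:
    size = spec.size
    disc = _disc_mask(size, spec.disc_radius)
    allowed = ndimage.binary_erosion(
        disc, structure=np.ones((3, 3), dtype=bool), iterations=_DISC_MARGIN
    )

    img = np.empty((size, size, 3), dtype=np.float64)
    img[:] = np.array(spec.background_intensity, dtype=np.float64)
    img[disc] = np.array(spec.disc_intensity, dtype=np.float64)

    vessel_masks = []
    disc_green = float(spec.disc_intensity[1])
    for pts, width, contrast in zip(centerlines, widths, contrasts):
        vmask = ndimage.binary_dilation(
            _rasterize_centerline(pts, size), structure=_disk_se((width - 1) / 2.0)
        )
        vmask &= allowed
        vessel_masks.append(vmask)
        # structure lives in the green channel only: red and blue stay flat
        value = max(disc_green - float(contrast), 0.0)
        img[..., 1][vmask] = np.minimum(img[..., 1][vmask], value)

    if spec.red_texture_sigma > 0:
        # choroidal background texture shows through the red channel of real
        # fundus photos; it pollutes a luminance conversion but not the green
        # plane.  Band-limited noise: white field smoothed at texture scale,
        # renormalized to the requested amplitude, confined to the disc.
        field = ndimage.gaussian_filter(
            rng.normal(0.0, 1.0, (size, size)), spec.red_texture_scale
        )
        field *= spec.red_texture_sigma / max(field.std(), 1e-12)
        img[..., 0][disc] += field[disc]
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)

    region = np.zeros((size, size), dtype=bool)
    for vmask in vessel_masks:
        region |= vmask
    truth = PhantomTruth(
        vessel_region_mask=region,
        vessel_boundary_map=mask_boundary(region) & disc,
        retina_disc_mask=disc,
        vessel_masks=vessel_masks,
        vessel_contrasts=[float(c) for c in contrasts],
        vessel_widths=[int(w) for w in widths],
        centerlines=centerlines,
    )
    return img, truth


def generate(spec: PhantomSpec = PhantomSpec()) -> tuple[np.ndarray, PhantomTruth]:
    """Generate a phantom image and its ground truth, fully determined by
    ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    center = (size - 1) / 2.0
    max_r = 0.88 * spec.disc_radius

    if spec.widths is not None:
        widths = [int(w) for w in spec.widths]
    else:
        lo, hi = spec.vessel_width_range
        widths = [int(rng.integers(lo, hi + 1)) for _ in range(spec.n_vessels)]
    if spec.contrasts is not None:
        contrasts = [float(c) for c in spec.contrasts]
    else:
        lo, hi = spec.vessel_contrast_range
        contrasts = [float(rng.uniform(lo, hi)) for _ in range(spec.n_vessels)]
    if len(widths) != spec.n_vessels or len(contrasts) != spec.n_vessels:
        raise ParameterError("explicit widths/contrasts must match n_vessels")

    centerlines: list[np.ndarray] = []
    all_widths: list[int] = []
    all_contrasts: list[float] = []
    for i in range(spec.n_vessels):
        r0 = rng.uniform(0.0, 0.2 * spec.disc_radius)
        a0 = rng.uniform(0.0, 2 * np.pi)
        start = np.array(
            [center + r0 * np.sin(a0), center + r0 * np.cos(a0)]
        )
        heading = a0 + rng.normal(0.0, 0.4)
        walk = _random_walk(rng, start, heading, max_r, center)
        pts = _spline_points(walk)
        centerlines.append(pts)
        all_widths.append(widths[i])
        all_contrasts.append(contrasts[i])
        if rng.uniform() < spec.branch_prob and len(walk) >= 6:
            j = int(rng.integers(len(walk) // 3, len(walk) - 2))
            bstart = walk[j]
            bheading = np.arctan2(*(walk[j + 1] - walk[j])) + rng.choice(
                [-1.0, 1.0]
            ) * rng.uniform(0.5, 0.9)
            branch = _random_walk(rng, bstart, bheading, max_r, center)
            centerlines.append(_spline_points(branch))
            all_widths.append(max(1, widths[i] - 1))
            all_contrasts.append(contrasts[i])

    return _compose(spec, centerlines, all_widths, all_contrasts, rng)


def two_vessel_phantom(
    seed: int = 0,
    size: int = 192,
    contrasts: tuple[float, float] = (80.0, 20.0),
    widths: tuple[int, int] = (5, 3),
    noise_sigma: float = 6.0,
) -> tuple[np.ndarray, PhantomTruth]:
    """Phantom with exactly two well-separated vessels of fixed contrast.

    One near-vertical vessel in each half of the disc, gently wavy, with the
    given green-channel contrasts (default 4:1 ratio: one prominent vessel
    and one faint one whose gradient response sits near the noise floor).
    Used to exercise per-region thresholding: thresholds low enough to trace
    the faint vessel admit noise edges elsewhere, so no single global
    threshold pair suits both vessels.
    """
    spec = PhantomSpec(
        seed=seed,
        size=size,
        contrasts=tuple(float(c) for c in contrasts),
        widths=tuple(int(w) for w in widths),
        n_vessels=2,
        noise_sigma=noise_sigma,
        branch_prob=0.0,
    )
    rng = np.random.default_rng(seed)
    center = (size - 1) / 2.0
    half_span = 0.8 * spec.disc_radius
    centerlines = []
    for k, xoff in enumerate((-0.35, 0.35)):
        rows = np.linspace(center - half_span, center + half_span, 9)
        amp = rng.uniform(4.0, 8.0)
        phase = rng.uniform(0.0, 2 * np.pi)
        cols = (
            center
            + xoff * spec.disc_radius
            + amp * np.sin(np.linspace(0, 2.2, 9) + phase)
            + rng.normal(0.0, 0.8, 9)
        )
        centerlines.append(_spline_points(np.stack([rows, cols], axis=1)))
    return _compose(spec, centerlines, list(spec.widths), list(spec.contrasts), rng)


def save_phantom(outdir, img: np.ndarray, truth: PhantomTruth, spec: PhantomSpec) -> dict:
    """Write the phantom image, truth maps and a JSON sidecar of the spec."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": outdir / "phantom.png",
        "vessel_mask": outdir / "vessel_mask.png",
        "vessel_boundary": outdir / "vessel_boundary.png",
        "disc_mask": outdir / "disc_mask.png",
        "spec": outdir / "phantom_spec.json",
    }
    write_color_image(paths["image"], img)
    write_mask(paths["vessel_mask"], truth.vessel_region_mask)
    write_mask(paths["vessel_boundary"], truth.vessel_boundary_map)
    write_mask(paths["disc_mask"], truth.retina_disc_mask)
    sidecar = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(spec).items()
    }
    sidecar["vessel_contrasts"] = truth.vessel_contrasts
    sidecar["vessel_widths"] = truth.vessel_widths
    paths["spec"].write_text(json.dumps(sidecar, indent=2))
    return paths
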