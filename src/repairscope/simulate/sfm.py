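"""Synthetic scanning-force-microscopy height images.

Draws protein particles of known volume, oligomer class and shape
(compact disc, rod, extended core-plus-arms) onto a flat field, applies
tip broadening as volume-preserving Gaussian smoothing, then adds the
scan artifacts a real image carries: a background plane tilt, per-scan-
line offsets and Gaussian height noise.  The assigned volume of every
particle equals the integral of its pre-broadening template exactly, so
volumetry is testable against ground truth.

Default geometry follows tapping-mode imaging of protein on mica:
2 x 2 um scans at 512 x 512 pixels (3.90625 nm/px).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .._geometry import mask_solidity
from ..sfm import HeightImage

OLIGOMER_CLASSES = ("monomer", "dimer", "3-4mer", ">tetramer")
SHAPE_CLASSES = ("compact", "rod", "extended")

# volume multipliers (units of the monomer reference volume) sampled per
# class; kept away from the classification bin edges 0.5/1.5/3/6 so that
# the few-percent volume loss of thresholded integration cannot flip a
# particle's class
CLASS_MULTIPLIER_RANGES = {
    "monomer": (0.75, 1.35),
    "dimer": (1.7, 2.7),
    "3-4mer": (3.4, 5.3),
    ">tetramer": (7.0, 14.0),
}

__all__ = [
    "OLIGOMER_CLASSES",
    "SHAPE_CLASSES",
    "CLASS_MULTIPLIER_RANGES",
    "SFMSimParams",
    "simulate_sfm_image",
]


@dataclass
class SFMSimParams:
    """Configuration of the height-map generator.

    ``class_mixture`` gives probabilities over oligomer classes
    (monomer, dimer, 3-4mer, >tetramer); ``shape_mixture`` over
    (compact, rod, extended).  ``free_rad51_fraction`` is the proportion
    of the ``n_particles`` that are small contaminant particles of
    ``contaminant_volume`` (nm^3).  ``plane_tilt`` is the full
    height drop of the background plane across one image width (nm).
    """

    pixel_size: float = 3.90625
    image_size: int = 512
    monomer_volume: float = 418.0
    class_mixture: tuple[float, float, float, float] = (0.08, 0.10, 0.12, 0.70)
    shape_mixture: tuple[float, float, float] = (0.6, 0.25, 0.15)
    tip_sigma: float = 3.0
    plane_tilt: float = 2.0
    line_offset_sigma: float = 0.15
    height_noise_sigma: float = 0.08
    n_particles: int = 40
    free_rad51_fraction: float = 0.0
    contaminant_volume: float = 56.0
    extended_solidity: float = 0.75
    footprint_radius_nm: float = 10.0
    rod_axis_ratio_range: tuple[float, float] = (1.8, 3.5)
    arm_width_px: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("class_mixture", "shape_mixture"):
            p = np.asarray(getattr(self, name), dtype=float)
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name} must be probabilities summing to 1")
        if self.monomer_volume <= 0:
            raise ValueError("monomer_volume must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if not 0.0 <= self.free_rad51_fraction <= 1.0:
            raise ValueError("free_rad51_fraction must be in [0, 1]")


def _local_grid(half: int) -> tuple[np.ndarray, np.ndarray]:
    ax = np.arange(-half, half + 1, dtype=float)
    return np.meshgrid(ax, ax, indexing="ij")


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _dome(radius_px: float, edge_px: float = 1.5) -> np.ndarray:
    """Flat-topped disc of unit height with a smooth edge roll-off.

    Protein particles image as plateau-like blobs (roughly uniform
    molecular thickness), so the thresholded footprint matches the
    template footprint for any threshold below the plateau.
    """
    half = int(np.ceil(radius_px)) + 1
    yy, xx = _local_grid(half)
    r = np.hypot(yy, xx)
    return _smoothstep((radius_px - r) / min(edge_px, radius_px / 2))


def _dist_to_segment(yy, xx, p0, p1):
    d = np.array(p1) - np.array(p0)
    L2 = d @ d
    t = ((yy - p0[0]) * d[0] + (xx - p0[1]) * d[1]) / max(L2, 1e-12)
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(yy - (p0[0] + t * d[0]), xx - (p0[1] + t * d[1]))


def _rod(footprint_area_px: float, axis_ratio: float, theta: float) -> np.ndarray:
    """Stadium-shaped rod with the given major/minor axis ratio."""
    w = np.sqrt(footprint_area_px / (axis_ratio - 1.0 + np.pi / 4.0))
    spine = w * (axis_ratio - 1.0)
    half = int(np.ceil((spine + w) / 2)) + 2
    yy, xx = _local_grid(half)
    u = np.array([np.sin(theta), np.cos(theta)])
    p0, p1 = -0.5 * spine * u, 0.5 * spine * u
    d = _dist_to_segment(yy, xx, p0, p1)
    return _smoothstep((w / 2 - d) / min(1.5, w / 4))


def _extended(core_r: float, arm_w: float, arm_len: float, theta0: float) -> np.ndarray:
    """Core dome with three radial arms (the low-solidity shape)."""
    half = int(np.ceil(core_r + arm_len)) + 2
    yy, xx = _local_grid(half)
    r = np.hypot(yy, xx)
    h = _smoothstep((core_r - r) / min(1.5, core_r / 2))
    for k in range(3):
        th = theta0 + 2.0 * np.pi * k / 3.0
        u = np.array([np.sin(th), np.cos(th)])
        p0 = 0.5 * core_r * u
        p1 = (core_r + arm_len) * u
        d = _dist_to_segment(yy, xx, p0, p1)
        arm = _smoothstep((arm_w / 2 - d) / min(1.5, arm_w / 4))
        h = np.maximum(h, arm)
    return h


_CAL_ANGLES = (0.0, 0.7, 1.4)  # arm pattern repeats every 2*pi/3


def _mean_solidity(core_r: float, arm_w: float, arm_len: float) -> float:
    return float(np.mean([mask_solidity(_extended(core_r, arm_w, arm_len, th) > 0) for th in _CAL_ANGLES]))


@lru_cache(maxsize=256)
def _solve_arm_length(core_r: float, arm_w: float, target_solidity: float) -> float:
    """Arm length whose orientation-averaged template solidity matches the target."""
    lo, hi = 0.5, 8.0 * core_r
    if _mean_solidity(core_r, arm_w, hi) > target_solidity:
        return hi
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        if _mean_solidity(core_r, arm_w, mid) > target_solidity:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _template(params: SFMSimParams, volume: float, shape: str, rng: np.random.Generator) -> np.ndarray:
    """Height template (nm) whose integral * pixel_size^2 equals ``volume``."""
    px = params.pixel_size
    r_fp = params.footprint_radius_nm * (volume / params.monomer_volume) ** (1.0 / 3.0) / px
    r_fp = max(r_fp, 1.8)
    if shape == "compact":
        h = _dome(r_fp)
    elif shape == "rod":
        ratio = rng.uniform(*params.rod_axis_ratio_range)
        h = _rod(np.pi * r_fp**2, ratio, rng.uniform(0, np.pi))
    elif shape == "extended":
        arm_len = _solve_arm_length(round(r_fp, 2), params.arm_width_px, round(params.extended_solidity, 3))
        h = _extended(round(r_fp, 2), params.arm_width_px, arm_len, rng.uniform(0, 2 * np.pi))
    else:
        raise ValueError(f"unknown shape {shape!r}")
    return h * (volume / (h.sum() * px**2))


def simulate_sfm_image(params: SFMSimParams) -> tuple[HeightImage, pd.DataFrame]:
    """Render one synthetic height image plus its ground-truth table.

    The table records, per particle: centre (px), assigned volume (nm^3),
    oligomer class, shape, and the solidity of the pre-noise template
    mask.  Raises ValueError if the requested particles cannot be placed
    without overlap after bounded retries.
    """
    rng = np.random.default_rng([params.seed, 2])
    n_img = params.image_size
    px = params.pixel_size

    n_contaminant = int(round(params.free_rad51_fraction * params.n_particles))
    specs: list[tuple[float, str, str]] = []
    for _ in range(params.n_particles - n_contaminant):
        cls = OLIGOMER_CLASSES[rng.choice(4, p=np.asarray(params.class_mixture))]
        shape = SHAPE_CLASSES[rng.choice(3, p=np.asarray(params.shape_mixture))]
        lo, hi = CLASS_MULTIPLIER_RANGES[cls]
        specs.append((params.monomer_volume * rng.uniform(lo, hi), cls, shape))
    for _ in range(n_contaminant):
        specs.append((params.contaminant_volume, "contaminant", "compact"))

    field_img = np.zeros((n_img, n_img))
    placed: list[tuple[float, float, float]] = []  # (row, col, radius_px)
    records = []
    pad = 4.0 * params.tip_sigma / px + 3.0
    for pid, (volume, cls, shape) in enumerate(specs):
        tpl = _template(params, volume, shape, rng)
        r_tpl = tpl.shape[0] // 2
        margin = r_tpl + pad
        if 2 * margin >= n_img:
            raise ValueError("particle footprint does not fit in the image")
        ok = False
        for _ in range(400):
            row = rng.uniform(margin, n_img - margin)
            col = rng.uniform(margin, n_img - margin)
            if all(np.hypot(row - r, col - c) > r_tpl + rr + 2 for r, c, rr in placed):
                ok = True
                break
        if not ok:
            raise ValueError("could not place all particles without overlap")
        placed.append((row, col, r_tpl))
        ir, ic = int(round(row)), int(round(col))
        field_img[ir - r_tpl : ir + r_tpl + 1, ic - r_tpl : ic + r_tpl + 1] += tpl
        records.append(
            {
                "particle_id": pid,
                "row_px": ir,
                "col_px": ic,
                "volume_nm3": volume,
                "oligomer_class": cls,
                "shape": shape,
                "true_solidity": mask_solidity(tpl > 0),
            }
        )

    if params.tip_sigma > 0:
        field_img = gaussian_filter(field_img, params.tip_sigma / px, mode="constant")

    if params.plane_tilt != 0.0:
        phi = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:n_img, 0:n_img]
        field_img = field_img + params.plane_tilt * (np.cos(phi) * xx + np.sin(phi) * yy) / n_img
    if params.line_offset_sigma > 0:
        field_img = field_img + rng.normal(0.0, params.line_offset_sigma, size=n_img)[:, None]
    if params.height_noise_sigma > 0:
        field_img = field_img + rng.normal(0.0, params.height_noise_sigma, size=field_img.shape)

    image = HeightImage(
        data=field_img,
        pixel_size=px,
        metadata={"scan_size_nm": n_img * px, "source": "synthetic", "seed": params.seed},
    )
    return image, pd.DataFrame.from_records(records)
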