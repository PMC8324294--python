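"""Scanning-force-microscopy particle morphometry.

Takes a raw height image (nm), flattens the scan background (per-line
offsets plus a global plane, both estimated on particle-free pixels),
segments particles by a height threshold, and measures per-particle
volume, area, solidity and axis ratio.  Particles are then classified by
shape (rod vs globular) and by oligomeric state in units of a monomer
reference volume, with small contaminants (e.g. free RAD51, monomer
volume 56 nm^3) excluded below a volume threshold.

Volume is integrated height times pixel area.  Solidity is the mask area
divided by the area of the convex hull that encloses the molecule (hull
computed on pixel corners; see :mod:`repairscope._geometry`), on a 0-1
scale where ~1 is globular and lower values mean extended/irregular.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from skimage.measure import label
from skimage.segmentation import clear_border

from ._geometry import convex_hull_area, ellipse_axis_ratio, mask_solidity

OLIGOMER_BIN_EDGES = (0.5, 1.5, 3.0, 6.0)  # in units of the monomer volume

__all__ = [
    "HeightImage",
    "ParticleRecord",
    "MonomerReference",
    "flatten_background",
    "segment_particles",
    "particle_metrics",
    "classify_shape",
    "classify_oligomer",
    "calibrate_monomer_volume",
    "population_summary",
    "analyze_height_image",
]


@dataclass
class HeightImage:
    """A 2D topography map in nm with its lateral pixel size (nm/px)."""

    data: np.ndarray
    pixel_size: float = 3.90625
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("height data must be 2D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("height data must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


@dataclass
class ParticleRecord:
    """Morphometric measurements of one segmented particle."""

    particle_id: int
    coords: np.ndarray  # (n, 2) pixel indices (row, col)
    centroid: tuple[float, float]
    area: float  # nm^2
    volume: float  # nm^3
    solidity: float
    axis_ratio: float
    shape_class: str = ""
    oligomer_class: str = ""


@dataclass
class MonomerReference:
    """Monomer reference volume and the contaminant-exclusion threshold.

    ``v1`` is the construct's monomer volume in nm^3 (a measured,
    calibration-dependent quantity; see :func:`calibrate_monomer_volume`).
    ``exclusion_threshold`` removes free contaminant protein: the default
    100 nm^3 sits above the RAD51 monomer volume (56 nm^3) and below any
    plausible half monomer volume.
    """

    construct: str = "full-length"
    v1: float = 418.0
    rad51_volume: float = 56.0
    exclusion_threshold: float = 100.0

    def __post_init__(self) -> None:
        if not self.v1 > self.exclusion_threshold > 0:
            raise ValueError("require v1 > exclusion_threshold > 0")


def _coarse_particle_mask(residual: np.ndarray, k_mad: float = 4.0) -> np.ndarray:
    med = np.median(residual)
    mad = np.median(np.abs(residual - med))
    return residual > med + k_mad * 1.4826 * max(mad, 1e-12)


def _plane_fit(img: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """Least-squares plane fitted on ``keep`` pixels, evaluated everywhere."""
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    A = np.stack([xx[keep], yy[keep], np.ones(keep.sum())], axis=1)
    coef, *_ = np.linalg.lstsq(A, img[keep], rcond=None)
    return coef[0] * xx + coef[1] * yy + coef[2]


def flatten_background(image: HeightImage, coarse_cut_mad: float = 4.0, n_iter: int = 2) -> HeightImage:
    """Remove per-scan-line offsets and the global background plane.

    Particles are pre-masked by a robust (MAD-based) height cut so they do
    not bias the background estimate; line offsets are the medians of the
    particle-free pixels of each scan line.  The output background median
    is zero.  Raises ValueError when no background pixels remain.
    """
    img = image.data.copy()
    for _ in range(n_iter):
        plane = _plane_fit(img, np.ones_like(img, dtype=bool))
        particles = _coarse_particle_mask(img - plane, coarse_cut_mad)
        background = ~particles
        if not background.any() or np.any(background.sum(axis=1) == 0):
            raise ValueError("no background pixels available for flattening")
        masked = np.where(background, img, np.nan)
        img = img - np.nanmedian(masked, axis=1)[:, None]
        img = img - _plane_fit(img, background)
    particles = _coarse_particle_mask(img, coarse_cut_mad)
    img -= np.median(img[~particles])
    return HeightImage(data=img, pixel_size=image.pixel_size, metadata={**image.metadata, "flattened": True})


def segment_particles(image: HeightImage, height_threshold: float = 0.5, min_area: int = 10) -> list[np.ndarray]:
    """8-connected components above the height threshold, as boolean masks.

    Components smaller than ``min_area`` pixels or touching the image
    border are discarded.
    """
    binary = image.data > height_threshold
    labels = label(binary, connectivity=2)
    labels = clear_border(labels)
    masks = []
    for lab in range(1, labels.max() + 1):
        mask = labels == lab
        if mask.sum() >= min_area:
            masks.append(mask)
    return masks


def particle_metrics(mask: np.ndarray, image: HeightImage, pixel_size: float | None = None, particle_id: int = 0) -> ParticleRecord:
    """Measure volume, area, solidity and axis ratio of one particle.

    volume = sum of heights over the mask * pixel_size^2;
    area = pixel count * pixel_size^2;
    solidity = pixel count / convex-hull area (hull on pixel corners,
    shoelace area);  axis_ratio = major/minor axis of the second-moment
    equivalent ellipse.  Masks of fewer than 3 pixels have no meaningful
    hull and raise ValueError.
    """
    px = image.pixel_size if pixel_size is None else pixel_size
    n_pix = int(np.count_nonzero(mask))
    if n_pix < 3:
        raise ValueError("mask must contain at least 3 pixels for solidity")
    if label(mask, connectivity=2).max() != 1:
        raise ValueError("mask must be a single connected component")
    rows, cols = np.nonzero(mask)
    volume = float(image.data[mask].sum()) * px**2
    area = n_pix * px**2
    return ParticleRecord(
        particle_id=particle_id,
        coords=np.stack([rows, cols], axis=1),
        centroid=(float(rows.mean()), float(cols.mean())),
        area=area,
        volume=volume,
        solidity=mask_solidity(mask),
        axis_ratio=ellipse_axis_ratio(mask),
    )


def classify_shape(record: ParticleRecord, rod_axis_ratio: float = 1.5) -> str:
    """'rod' iff the axis ratio strictly exceeds 1.5, else 'globular'."""
    return "rod" if record.axis_ratio > rod_axis_ratio else "globular"


def classify_oligomer(record: ParticleRecord | float, ref: MonomerReference) -> str:
    """Bin a measured volume into oligomeric classes in units of v1.

    Volumes below the exclusion threshold, or below half the monomer
    volume, are 'excluded' (free contaminant protein); the remaining bins
    are [0.5, 1.5) monomer, [1.5, 3) dimer, [3, 6) 3-4mer, >= 6 >tetramer.
    """
    volume = record.volume if isinstance(record, ParticleRecord) else float(record)
    if volume < ref.exclusion_threshold:
        return "excluded"
    q = volume / ref.v1
    if q < OLIGOMER_BIN_EDGES[0]:
        return "excluded"
    if q < OLIGOMER_BIN_EDGES[1]:
        return "monomer"
    if q < OLIGOMER_BIN_EDGES[2]:
        return "dimer"
    if q < OLIGOMER_BIN_EDGES[3]:
        return "3-4mer"
    return ">tetramer"


def calibrate_monomer_volume(volumes: np.ndarray, exclusion_threshold: float = 100.0, cluster_width: float = 1.5) -> float:
    """Monomer reference volume from a monomer-rich control set.

    Finds the lowest substantial mode of the log-volume density (Gaussian
    KDE) among volumes above the exclusion threshold and returns the
    median of the volumes within ``cluster_width``-fold of that mode.
    """
    v = np.asarray(volumes, dtype=float)
    v = v[v > exclusion_threshold]
    if v.size < 5:
        raise ValueError("too few volumes to calibrate")
    logv = np.log(v)
    kde = gaussian_kde(logv)
    grid = np.linspace(logv.min(), logv.max(), 512)
    dens = kde(grid)
    peaks = [i for i in range(1, len(grid) - 1) if dens[i] >= dens[i - 1] and dens[i] >= dens[i + 1]]
    if not peaks:
        peaks = [int(np.argmax(dens))]
    substantial = [i for i in peaks if dens[i] >= 0.2 * dens.max()]
    mode = float(np.exp(grid[min(substantial)]))
    cluster = v[(v >= mode / cluster_width) & (v <= mode * cluster_width)]
    return float(np.median(cluster))


def population_summary(records: list[ParticleRecord]) -> dict[str, pd.DataFrame | float]:
    """Distribution tables over a measured particle population.

    Returns per-oligomer-class fractions (excluded particles omitted from
    the denominator), a solidity histogram with 0.05-wide bins on [0, 1],
    the rod fraction, and the joint oligomer x solidity-bin table.
    Raises ValueError when every record is excluded.
    """
    classified = [r for r in records if r.oligomer_class not in ("", "excluded")]
    if not classified:
        raise ValueError("all records are excluded")
    classes = ["monomer", "dimer", "3-4mer", ">tetramer"]
    counts = pd.Series([r.oligomer_class for r in classified]).value_counts()
    fractions = pd.DataFrame(
        {
            "oligomer_class": classes,
            "count": [int(counts.get(c, 0)) for c in classes],
        }
    )
    fractions["fraction"] = fractions["count"] / len(classified)

    edges = np.round(np.arange(0.0, 1.0001, 0.05), 10)
    solidity = np.array([r.solidity for r in classified])
    hist, _ = np.histogram(solidity, bins=edges)
    solidity_hist = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": hist})

    rod_fraction = float(np.mean([classify_shape(r) == "rod" for r in classified]))

    bin_idx = np.clip(np.digitize(solidity, edges) - 1, 0, len(edges) - 2)
    joint = pd.crosstab(
        pd.Series([r.oligomer_class for r in classified], name="oligomer_class"),
        pd.Series(edges[:-1][bin_idx], name="solidity_bin"),
    )
    return {
        "class_fractions": fractions,
        "solidity_histogram": solidity_hist,
        "rod_fraction": rod_fraction,
        "joint": joint,
        "n_classified": len(classified),
        "n_excluded": len(records) - len(classified),
    }


def analyze_height_image(
    image: HeightImage,
    ref: MonomerReference,
    height_threshold: float = 0.5,
    min_area: int = 10,
    flatten: bool = True,
) -> list[ParticleRecord]:
    """Full per-image pipeline: flatten, segment, measure, classify."""
    flat = flatten_background(image) if flatten else image
    records = []
    for i, mask in enumerate(segment_particles(flat, height_threshold, min_area)):
        rec = particle_metrics(mask, flat, particle_id=i)
        rec.shape_class = classify_shape(rec)
        rec.oligomer_class = classify_oligomer(rec, ref)
        records.append(rec)
    return records


def records_to_frame(records: list[ParticleRecord]) -> pd.DataFrame:
    """Per-particle CSV-ready table."""
    return pd.DataFrame(
        [
            {
                "particle_id": r.particle_id,
                "row_px": r.centroid[0],
                "col_px": r.centroid[1],
                "area_nm2": r.area,
                "volume_nm3": r.volume,
                "solidity": r.solidity,
                "axis_ratio": r.axis_ratio,
                "shape_class": r.shape_class,
                "oligomer_class": r.oligomer_class,
            }
            for r in records
        ]
    )
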