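"""Particle detection and track linking for single-molecule movies.

Molecules are identified per frame as local intensity maxima above a
fixed threshold inside a manually drawn nuclear mask, refined to
sub-pixel position by a least-squares 2D Gaussian fit (centroid fallback),
and linked frame-to-frame by greedy ascending-distance nearest-neighbour
assignment with a maximum displacement of 1.2 um and a maximum gap of
one frame; tracks shorter than five detections are discarded.

Coordinates are physical: x = column * pixel_size, y = row * pixel_size,
0-based pixel indices, origin at the top-left.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from skimage.feature import peak_local_max

__all__ = [
    "Localization",
    "LinkingParams",
    "Track",
    "background_threshold",
    "detect_spots",
    "link_tracks",
    "filter_tracks",
]


@dataclass
class Localization:
    """One sub-pixel detection: frame index, position (um), intensity (au)."""

    frame: int
    x: float
    y: float
    intensity: float


@dataclass
class LinkingParams:
    """Nearest-neighbour linking rules (displacement cap, gap, min length)."""

    max_displacement: float = 1.2  # um
    max_gap: int = 1  # frames
    min_track_length: int = 5  # detections

    def __post_init__(self) -> None:
        if self.max_displacement <= 0:
            raise ValueError("max_displacement must be > 0")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.min_track_length < 2:
            raise ValueError("min_track_length must be >= 2")


@dataclass
class Track:
    """Ordered localizations of one particle, possibly spanning gaps."""

    track_id: int
    localizations: list[Localization] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.localizations)

    @property
    def frames(self) -> np.ndarray:
        return np.array([l.frame for l in self.localizations])

    @property
    def x(self) -> np.ndarray:
        return np.array([l.x for l in self.localizations])

    @property
    def y(self) -> np.ndarray:
        return np.array([l.y for l in self.localizations])

    @property
    def gap_frames(self) -> list[int]:
        f = self.frames
        return [g for a, b in zip(f[:-1], f[1:]) for g in range(a + 1, b)]


def background_threshold(frame: np.ndarray, mask: np.ndarray, k: float = 6.0) -> float:
    """Fixed intensity threshold helper: mean + k * sd of masked pixels."""
    vals = frame[mask.astype(bool)]
    if vals.size == 0:
        raise ValueError("empty mask")
    return float(vals.mean() + k * vals.std())


def _gauss2d(coords, amp, x0, y0, sigma, offset):
    xx, yy = coords
    return (amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma**2)) + offset).ravel()


def _refine_subpixel(frame: np.ndarray, row: int, col: int, half: int = 3) -> tuple[float, float, float]:
    """Least-squares Gaussian fit in a (2*half+1)^2 window; centroid fallback.

    Returns (col, row) sub-pixel position and the background-corrected
    integrated intensity of the spot.
    """
    h, w = frame.shape
    r0, r1 = max(0, row - half), min(h, row + half + 1)
    c0, c1 = max(0, col - half), min(w, col + half + 1)
    win = frame[r0:r1, c0:c1].astype(float)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    offset0 = float(win.min())
    amp0 = float(win.max() - offset0)
    try:
        popt, _ = curve_fit(
            _gauss2d,
            (xx, yy),
            win.ravel(),
            p0=[amp0, col, row, 1.3, offset0],
            bounds=([0, c0 - 1, r0 - 1, 0.3, -np.inf], [np.inf, c1, r1, half + 2, np.inf]),
            maxfev=400,
        )
        amp, x0, y0, sigma, _ = popt
        return float(x0), float(y0), float(2 * np.pi * amp * sigma**2)
    except Exception:
        wsub = np.clip(win - np.median(win), 0, None)
        total = wsub.sum()
        if total <= 0:
            return float(col), float(row), 0.0
        return float((wsub * xx).sum() / total), float((wsub * yy).sum() / total), float(total)


def detect_spots(
    frame_image: np.ndarray,
    nucleus_mask: np.ndarray,
    intensity_threshold: float,
    pixel_size: float = 0.1,
    psf_sigma_px: float = 1.0,
    frame: int = 0,
) -> list[Localization]:
    """Detect molecules in one frame inside the nuclear mask.

    Candidate pixels are local maxima above the fixed threshold inside
    the mask; each is refined to sub-pixel position; detections closer
    than one PSF width are merged into the brighter one.
    """
    mask = np.asarray(nucleus_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty nucleus mask")
    if mask.shape != frame_image.shape:
        raise ValueError("mask shape must match frame shape")
    if intensity_threshold < 0:
        raise ValueError("intensity_threshold must be >= 0")
    labels = mask.astype(int)
    peaks = peak_local_max(
        np.asarray(frame_image, dtype=float),
        min_distance=1,
        threshold_abs=intensity_threshold,
        labels=labels,
        exclude_border=False,
    )
    locs: list[Localization] = []
    for row, col in peaks:
        x_px, y_px, intensity = _refine_subpixel(np.asarray(frame_image, dtype=float), int(row), int(col))
        locs.append(Localization(frame=frame, x=x_px * pixel_size, y=y_px * pixel_size, intensity=intensity))
    # merge detections closer than one PSF width, keep the brighter
    locs.sort(key=lambda l: -l.intensity)
    merged: list[Localization] = []
    min_dist = psf_sigma_px * pixel_size
    for l in locs:
        if all(np.hypot(l.x - m.x, l.y - m.y) >= min_dist for m in merged):
            merged.append(l)
    merged.sort(key=lambda l: (l.y, l.x))
    return merged


def link_tracks(localizations: list[Localization] | dict[int, list[Localization]], params: LinkingParams | None = None) -> list[Track]:
    """Link detections into tracks by greedy global nearest neighbour.

    For each frame transition, candidate (track-end, detection) pairs
    within the displacement cap are processed in ascending distance (ties
    broken by lower track id), each end and detection used at most once.
    Track ends stay linkable across up to ``max_gap`` missing frames with
    the same displacement cap; unassigned detections start new tracks.
    Deterministic for a fixed input order.
    """
    if params is None:
        params = LinkingParams()
    if isinstance(localizations, dict):
        by_frame = {f: list(ls) for f, ls in localizations.items()}
    else:
        by_frame = {}
        for l in localizations:
            by_frame.setdefault(l.frame, []).append(l)
    tracks: list[Track] = []
    open_tracks: list[Track] = []
    for f in sorted(by_frame):
        dets = by_frame[f]
        open_tracks = [t for t in open_tracks if f - t.localizations[-1].frame <= params.max_gap + 1]
        pairs = []
        for t in open_tracks:
            last = t.localizations[-1]
            for j, d in enumerate(dets):
                dist = float(np.hypot(d.x - last.x, d.y - last.y))
                if dist <= params.max_displacement:
                    pairs.append((dist, t.track_id, t, j))
        pairs.sort(key=lambda p: (p[0], p[1]))
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for dist, tid, t, j in pairs:
            if tid in used_tracks or j in used_dets:
                continue
            t.localizations.append(dets[j])
            used_tracks.add(tid)
            used_dets.add(j)
        for j, d in enumerate(dets):
            if j not in used_dets:
                t = Track(track_id=len(tracks), localizations=[d])
                tracks.append(t)
                open_tracks.append(t)
    return tracks


def filter_tracks(tracks: list[Track], params: LinkingParams | None = None) -> list[Track]:
    """Drop tracks with fewer than ``min_track_length`` detections."""
    if params is None:
        params = LinkingParams()
    return [t for t in tracks if len(t) >= params.min_track_length]
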