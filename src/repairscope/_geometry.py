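"""Shared pixel-mask geometry: convex hull area, solidity, ellipse axes.

The convex hull is computed on the corner points of the mask's pixels
(each pixel treated as a unit square), so a filled convex shape has
solidity exactly 1 and the hull area of a plus-shape of five unit squares
is 7.  Hull area uses the shoelace formula on the hull polygon.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull
from skimage.measure import regionprops

__all__ = ["pixel_corner_points", "shoelace_area", "convex_hull_area", "mask_solidity", "ellipse_axis_ratio"]


def pixel_corner_points(mask: np.ndarray) -> np.ndarray:
    """(N, 2) array of the corner coordinates of all pixels in the mask."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty mask")
    corners = np.concatenate(
        [
            np.stack([rows - 0.5, cols - 0.5], axis=1),
            np.stack([rows - 0.5, cols + 0.5], axis=1),
            np.stack([rows + 0.5, cols - 0.5], axis=1),
            np.stack([rows + 0.5, cols + 0.5], axis=1),
        ]
    )
    return np.unique(corners, axis=0)


def shoelace_area(vertices: np.ndarray) -> float:
    """Polygon area from ordered vertices via the shoelace formula."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def convex_hull_area(mask: np.ndarray) -> float:
    """Convex hull area (px^2) of a pixel mask, hull on pixel corners."""
    pts = pixel_corner_points(mask)
    hull = ConvexHull(pts)
    return shoelace_area(pts[hull.vertices])


def mask_solidity(mask: np.ndarray) -> float:
    """Pixel count of the mask divided by its corner-hull area; in (0, 1]."""
    return float(np.count_nonzero(mask)) / convex_hull_area(mask)


def ellipse_axis_ratio(mask: np.ndarray) -> float:
    """Major/minor axis ratio of the mask's second-moment equivalent ellipse.

    The minor axis is floored at one pixel so single-pixel-wide masks get a
    large but finite ratio.
    """
    props = regionprops(mask.astype(np.uint8))[0]
    minor = max(props.axis_minor_length, 1.0)
    major = max(props.axis_major_length, minor)
    return major / minor
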