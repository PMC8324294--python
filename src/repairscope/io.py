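"""Readers and writers for the standard interchange formats.

Movies and confocal stacks are multi-page TIFF; SFM height maps are
32-bit float TIFF (nm) or whitespace-delimited text matrices; tables are
CSV in long format with physical units (um / nm) and 0-based pixel
indices; run manifests are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .sfm import HeightImage
from .tracking import Localization, Track

TRACK_COLUMNS = ["cell_id", "track_id", "tracklet_id", "frame", "x_um", "y_um", "intensity", "state"]

__all__ = [
    "TRACK_COLUMNS",
    "save_movie",
    "load_movie",
    "save_height_image",
    "load_height_image",
    "tracks_to_frame",
    "frame_to_tracks",
    "save_config",
    "load_config",
    "write_manifest",
    "read_manifest",
]


def save_movie(path: str | Path, movie: np.ndarray) -> None:
    """Write a (frames, H, W) movie or stack as multi-page TIFF."""
    tifffile.imwrite(str(path), np.asarray(movie, dtype=np.float32))


def load_movie(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    return arr[None] if arr.ndim == 2 else arr


def save_height_image(path: str | Path, image: HeightImage) -> None:
    """Write a height map: float32 TIFF for .tif/.tiff, text matrix otherwise."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(
            str(path),
            image.data.astype(np.float32),
            metadata={"pixel_size_nm": image.pixel_size},
        )
    else:
        header = f"pixel_size_nm={image.pixel_size}"
        np.savetxt(path, image.data, header=header)


def load_height_image(path: str | Path, pixel_size: float | None = None) -> HeightImage:
    """Read a height map written by :func:`save_height_image`."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(str(path)) as tf:
            data = tf.asarray().astype(float)
            if pixel_size is None:
                meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
                pixel_size = float(meta.get("pixel_size_nm", 3.90625))
    else:
        with open(path) as fh:
            first = fh.readline()
        if pixel_size is None and "pixel_size_nm=" in first:
            pixel_size = float(first.split("pixel_size_nm=")[1])
        data = np.loadtxt(path)
        if pixel_size is None:
            pixel_size = 3.90625
    return HeightImage(data=data, pixel_size=pixel_size)


def tracks_to_frame(tracks: list[Track], cell_id: str = "", states: dict | None = None) -> pd.DataFrame:
    """Long-format track table: one row per localization.

    ``states`` optionally maps (track_id, frame) to a mobility-state
    label; unknown entries are written as empty strings.
    """
    rows = []
    for t in tracks:
        for loc in t.localizations:
            key = (t.track_id, loc.frame)
            state = states.get(key, ("", ""))[1] if states else ""
            tracklet = states.get(key, ("", ""))[0] if states else ""
            rows.append(
                {
                    "cell_id": cell_id,
                    "track_id": t.track_id,
                    "tracklet_id": tracklet,
                    "frame": loc.frame,
                    "x_um": loc.x,
                    "y_um": loc.y,
                    "intensity": loc.intensity,
                    "state": state,
                }
            )
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def frame_to_tracks(table: pd.DataFrame) -> list[Track]:
    """Rebuild Track objects from a long-format table (lossless fields)."""
    tracks = []
    for tid, grp in table.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        locs = [
            Localization(frame=int(r.frame), x=float(r.x_um), y=float(r.y_um), intensity=float(r.intensity))
            for r in grp.itertuples()
        ]
        tracks.append(Track(track_id=int(tid), localizations=locs))
    return tracks


def save_config(path: str | Path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_manifest(path: str | Path, *, inputs: list[str], outputs: list[str], parameters: dict, seed: int | None) -> None:
    """Machine-readable record of one run (inputs, outputs, params, seed)."""
    from . import __version__

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "inputs": sorted(str(p) for p in inputs),
        "outputs": sorted(str(p) for p in outputs),
        "parameters": parameters,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
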