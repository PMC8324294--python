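"""Synthetic confocal z-stacks with nuclei, foci and EdU labelling.

Emulates fixed-cell imaging of a repair protein: a DAPI channel with
filled nuclear discs, a focus channel carrying diffraction-limited 3D
Gaussian spots over a nuclear background, and an EdU channel with a
uniform per-nucleus signal at one of two levels (replicating vs not).
Default geometry follows the confocal acquisition: 11 z-slices at
500 nm spacing, 132 nm lateral pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FociSimParams", "simulate_foci_stack"]


@dataclass
class FociSimParams:
    """Configuration of the foci-stack generator.

    ``foci_count_distribution`` is either an int (fixed count per
    nucleus) or ``("poisson", mean)``.  ``edu_intensity_levels`` are the
    per-pixel EdU levels (negative, positive) in au; with the default
    nucleus sizes the integrated intensities fall well below / above the
    500 au gate.  ``focus_z_jitter`` (slices, sd) scatters foci axially
    around the centre slice; the default 0 reflects autofocus centring.
    """

    n_nuclei: int = 8
    nucleus_radius_range: tuple[float, float] = (16.0, 24.0)
    foci_count_distribution: int | tuple[str, float] = ("poisson", 10.0)
    focus_sigma: float = 1.2  # px, lateral
    focus_sigma_z: float = 1.0  # slices
    min_focus_separation: float = 5.0  # px; resolvable-spot spacing
    focus_z_jitter: float = 0.0  # slices
    focus_amplitude_range: tuple[float, float] = (30.0, 60.0)
    nuclear_background: float = 10.0
    dapi_level: float = 50.0
    noise_sigma: float = 2.0
    edu_positive_fraction: float = 0.4
    edu_intensity_levels: tuple[float, float] = (0.05, 2.0)
    edu_noise_sigma: float = 0.02
    z_slices: int = 11
    pixel_size: float = 132.0  # nm
    image_size: tuple[int, int] = (256, 256)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 0 or self.z_slices < 1:
            raise ValueError("counts must be non-negative and z_slices >= 1")
        if not 0.0 <= self.edu_positive_fraction <= 1.0:
            raise ValueError("edu_positive_fraction must be in [0, 1]")
        if self.nucleus_radius_range[0] > self.nucleus_radius_range[1]:
            raise ValueError("invalid nucleus_radius_range")


def _draw_count(dist, rng: np.random.Generator) -> int:
    if isinstance(dist, (int, np.integer)):
        return int(dist)
    kind, mean = dist
    if kind == "poisson":
        return int(rng.poisson(mean))
    raise ValueError(f"unknown count distribution {dist!r}")


def simulate_foci_stack(params: FociSimParams) -> tuple[dict[str, np.ndarray], pd.DataFrame, pd.DataFrame]:
    """Render per-channel (Z, H, W) stacks plus ground-truth tables.

    Returns ``(channels, nuclei, foci)`` where ``channels`` maps
    'dapi'/'focus'/'edu' to stacks, ``nuclei`` records centre, radius,
    EdU level/flag and focus count, and ``foci`` records position,
    amplitude and the integrated (noise-free, background-subtracted)
    intensity of each spot in the maximum projection.
    """
    rng = np.random.default_rng([params.seed, 3])
    h, w = params.image_size
    z = params.z_slices
    zc = (z - 1) / 2.0

    # place non-overlapping nuclei
    nuclei = []
    for nid in range(params.n_nuclei):
        radius = rng.uniform(*params.nucleus_radius_range)
        ok = False
        for _ in range(400):
            cy = rng.uniform(radius + 2, h - radius - 2)
            cx = rng.uniform(radius + 2, w - radius - 2)
            if all(np.hypot(cy - n["cy"], cx - n["cx"]) > radius + n["radius"] + 4 for n in nuclei):
                ok = True
                break
        if not ok:
            raise ValueError("could not place all nuclei without overlap")
        edu_positive = bool(rng.uniform() < params.edu_positive_fraction)
        nuclei.append(
            {
                "nucleus_id": nid,
                "cy": cy,
                "cx": cx,
                "radius": radius,
                "edu_positive": edu_positive,
                "edu_level": params.edu_intensity_levels[1 if edu_positive else 0],
            }
        )

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dapi2d = np.zeros((h, w))
    edu2d = np.zeros((h, w))
    focus_bg2d = np.zeros((h, w))
    for n in nuclei:
        disc = (yy - n["cy"]) ** 2 + (xx - n["cx"]) ** 2 <= n["radius"] ** 2
        dapi2d[disc] = params.dapi_level
        edu2d[disc] = n["edu_level"]
        focus_bg2d[disc] = params.nuclear_background

    focus_clean = np.tile(focus_bg2d, (z, 1, 1))
    foci_rows = []
    fid = 0
    for n in nuclei:
        count = _draw_count(params.foci_count_distribution, rng)
        placed = 0
        centers: list[tuple[float, float]] = []
        attempts = 0
        while placed < count:
            attempts += 1
            if attempts > 200 * max(count, 1):
                raise ValueError("could not place foci at the requested separation")
            r = n["radius"] * np.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * np.pi)
            fy, fx = n["cy"] + r * np.sin(th), n["cx"] + r * np.cos(th)
            if (fy - n["cy"]) ** 2 + (fx - n["cx"]) ** 2 > (n["radius"] - 2) ** 2:
                continue
            if any(np.hypot(fy - py, fx - px_) < params.min_focus_separation for py, px_ in centers):
                continue
            centers.append((fy, fx))
            fz = zc + (rng.normal(0, params.focus_z_jitter) if params.focus_z_jitter > 0 else 0.0)
            amp = rng.uniform(*params.focus_amplitude_range)
            spot2d = amp * np.exp(
                -(((yy - fy) ** 2 + (xx - fx) ** 2) / (2 * params.focus_sigma**2))
            )
            zprof = np.exp(-((np.arange(z) - fz) ** 2) / (2 * params.focus_sigma_z**2))
            for iz in range(z):
                focus_clean[iz] += zprof[iz] * spot2d
            foci_rows.append(
                {
                    "focus_id": fid,
                    "nucleus_id": n["nucleus_id"],
                    "row_px": fy,
                    "col_px": fx,
                    "z": fz,
                    "amplitude": amp,
                    "integrated_intensity": float((zprof.max() * spot2d).sum()),
                }
            )
            fid += 1
            placed += 1
        n["n_foci"] = count

    def _stack(img2d: np.ndarray) -> np.ndarray:
        return np.tile(img2d, (z, 1, 1))

    channels_clean = {"dapi": _stack(dapi2d), "focus": focus_clean, "edu": _stack(edu2d)}
    channels = {}
    for name, stack in channels_clean.items():
        # the EdU channel gets its own (small) noise level: its per-pixel
        # signal is an order of magnitude below the stain channels and the
        # 500 au gate on the max projection must stay meaningful
        sigma = params.edu_noise_sigma if name == "edu" else params.noise_sigma
        noise = rng.normal(0.0, sigma, size=stack.shape) if sigma > 0 else 0.0
        channels[name] = stack + noise

    nuclei_df = pd.DataFrame(nuclei)
    if nuclei_df.empty:
        nuclei_df = pd.DataFrame(columns=["nucleus_id", "cy", "cx", "radius", "edu_positive", "edu_level", "n_foci"])
    foci_df = pd.DataFrame(foci_rows)
    if foci_df.empty:
        foci_df = pd.DataFrame(
            columns=["focus_id", "nucleus_id", "row_px", "col_px", "z", "amplitude", "integrated_intensity"]
        )
    return channels, nuclei_df, foci_df
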