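"""Calibrated recovery experiments at the study's imaging conditions.

Each experiment generates synthetic data whose ground truth equals a
characterized property of the full-length protein system — the mobility
composition of untreated and irradiated cells, the fast-state diffusion
coefficient, the oligomeric mixtures with and without RAD51, and the
low-solidity conformational mode — runs the corresponding analysis
pipeline end to end, and returns the recovered quantity.  They exist so
that parameter recovery can be checked against the values the pipelines
are expected to reproduce, at the acquisition geometry of the study
(32 ms frames / 100 nm px for tracking; 2x2 um / 512 px height maps).
"""

from __future__ import annotations

import numpy as np

from .mobility import analyze_cell_tracks
from .sfm import MonomerReference, analyze_height_image, calibrate_monomer_volume
from .simulate import SFMSimParams, SPTSimParams, simulate_sfm_image, simulate_tracks

# mobility composition of full-length protein (fraction of tracklets)
UNTREATED_IMMOBILE_FRACTION = 0.34
IRRADIATED_IMMOBILE_FRACTION = 0.41
FAST_STATE_D = 1.5  # um^2/s

# oligomeric mixtures (monomer, dimer, 3-4mer, >tetramer)
FULL_LENGTH_MIXTURE = (0.08, 0.10, 0.12, 0.70)  # alone: 70% above tetramer
RAD51_MIXTURE = (0.74, 0.18, 0.05, 0.03)  # + RAD51: largely monomeric

# solidity of the extended conformational mode (no ssDNA, low mode)
EXTENDED_SOLIDITY_MODE = 0.75

__all__ = [
    "UNTREATED_IMMOBILE_FRACTION",
    "IRRADIATED_IMMOBILE_FRACTION",
    "FAST_STATE_D",
    "FULL_LENGTH_MIXTURE",
    "RAD51_MIXTURE",
    "EXTENDED_SOLIDITY_MODE",
    "fast_diffusion_experiment",
    "immobile_fraction_experiment",
    "oligomer_experiment",
    "solidity_mode_experiment",
]


def _seeds(seed: int, n: int, stream: int) -> list[int]:
    ss = np.random.SeedSequence([seed, stream])
    return [int(s) for s in ss.generate_state(n) >> 1]  # keep < 2**31


def _cell_tracks(composition: tuple[float, float, float], n_particles: int, seed: int) -> list:
    """Single-state track mixture whose tracklet composition is exact.

    With an identity transition matrix every track is one ground-truth
    tracklet, so the immobile tracklet proportion equals the immobile
    mixture weight by construction.  Track lengths follow the bleaching
    lifetime (mean 40 frames).
    """
    p = SPTSimParams(
        n_particles=n_particles,
        n_frames=200,
        bleach_prob=1.0 / 40.0,
        transition_matrix=np.eye(3),
        initial_state_probs=list(composition),
        seed=seed,
    )
    return [t for t in simulate_tracks(p) if len(t) >= 10]


def immobile_fraction_experiment(
    immobile_fraction: float,
    seed: int,
    n_cells: int = 20,
    n_particles_per_cell: int = 420,
) -> tuple[float, list[float]]:
    """Recover the median per-cell immobile percentage for a composition.

    Each synthetic cell draws >= 300 usable tracklets with the requested
    ground-truth immobile proportion (remainder split equally between
    slow and fast); the full segmentation -> MSD -> classification ->
    per-cell summary pipeline then recomputes the immobile percentage.
    Returns (median, per-cell values).
    """
    rem = (1.0 - immobile_fraction) / 2.0
    composition = (immobile_fraction, rem, rem)
    fractions = []
    for s in _seeds(seed, n_cells, stream=11):
        tracks = _cell_tracks(composition, n_particles_per_cell, s)
        _, summary = analyze_cell_tracks(tracks, cell_id=str(s))
        fractions.append(summary.immobile_fraction)
    return float(np.median(fractions)), fractions


def fast_diffusion_experiment(seed: int, n_tracklets: int = 500) -> tuple[float, int]:
    """Mean D_app of fast-classified tracklets at the acquisition geometry.

    Simulates pure fast-state motion at the reference coefficient in a
    large nucleus, runs segmentation and MSD fitting, and averages D_app
    over the tracklets the pipeline classifies as fast.
    """
    collected = []
    mask = np.ones((256, 256), dtype=bool)
    for s in _seeds(seed, 6, stream=12):
        if len(collected) >= n_tracklets:
            break
        p = SPTSimParams(
            n_particles=n_tracklets // 4,
            n_frames=200,
            bleach_prob=1.0 / 40.0,
            transition_matrix=np.eye(3),
            initial_state_probs=[0.0, 0.0, 1.0],
            nucleus_mask=mask,
            seed=s,
        )
        tracks = [t for t in simulate_tracks(p) if len(t) >= 10]
        table, _ = analyze_cell_tracks(tracks)
        collected.extend(table.loc[table.mobility_class == "fast", "D_app"].tolist())
    collected = collected[: max(n_tracklets, len(collected))]
    return float(np.mean(collected)), len(collected)


def _measure_images(param_list: list[SFMSimParams], ref: MonomerReference | None = None):
    records = []
    for p in param_list:
        image, _ = simulate_sfm_image(p)
        records.extend(analyze_height_image(image, ref or MonomerReference()))
    return records


def calibrate_reference(seed: int, n_images: int = 4, particles_per_image: int = 40) -> MonomerReference:
    """Monomer reference volume measured on a monomer-only control set."""
    params = [
        SFMSimParams(n_particles=particles_per_image, class_mixture=(1.0, 0.0, 0.0, 0.0),
                     shape_mixture=(1.0, 0.0, 0.0), seed=s)
        for s in _seeds(seed, n_images, stream=13)
    ]
    volumes = np.array([r.volume for r in _measure_images(params)])
    return MonomerReference(v1=calibrate_monomer_volume(volumes))


def oligomer_experiment(
    mixture: tuple[float, float, float, float],
    seed: int,
    n_images: int = 10,
    particles_per_image: int = 35,
    free_rad51_fraction: float = 0.0,
    shape_mixture: tuple[float, float, float] = (0.6, 0.25, 0.15),
) -> tuple[dict[str, float], int]:
    """Recover oligomer-class percentages for a generated mixture.

    The monomer reference volume is first calibrated on a monomer-rich
    control image set (the measured quantity it is defined to be), then
    the condition images are flattened, segmented, measured and
    classified; percentages are among non-excluded particles.
    """
    ref = calibrate_reference(seed)
    if free_rad51_fraction > 0:
        particles_per_image = int(round(particles_per_image / (1.0 - free_rad51_fraction)))
    params = [
        SFMSimParams(n_particles=particles_per_image, class_mixture=mixture,
                     shape_mixture=shape_mixture, free_rad51_fraction=free_rad51_fraction, seed=s)
        for s in _seeds(seed, n_images, stream=14)
    ]
    records = [r for r in _measure_images(params, ref) if r.oligomer_class != "excluded"]
    n = len(records)
    percents = {
        cls: 100.0 * sum(r.oligomer_class == cls for r in records) / n
        for cls in ("monomer", "dimer", "3-4mer", ">tetramer")
    }
    return percents, n


def solidity_mode_experiment(
    seed: int,
    n_particles: int = 210,
    particles_per_image: int = 30,
    target_solidity: float = EXTENDED_SOLIDITY_MODE,
) -> tuple[float, np.ndarray, int]:
    """Mode of the measured solidity histogram for extended particles.

    Builds >= 200 core-plus-arms particles whose pre-noise template
    solidity is tuned to the target, renders them with scan artifacts,
    then segments and measures solidity; returns (modal bin centre,
    histogram, n particles measured) for 0.05-wide bins on [0, 1].
    """
    n_images = int(np.ceil(n_particles / particles_per_image))
    params = [
        SFMSimParams(n_particles=particles_per_image, class_mixture=(0.0, 0.0, 0.0, 1.0),
                     shape_mixture=(0.0, 0.0, 1.0), extended_solidity=target_solidity, seed=s)
        for s in _seeds(seed, n_images, stream=15)
    ]
    sols = np.array([r.solidity for r in _measure_images(params)])
    edges = np.round(np.arange(0.0, 1.0001, 0.05), 10)
    hist, _ = np.histogram(sols, bins=edges)
    mode_idx = int(np.argmax(hist))
    center = float(0.5 * (edges[mode_idx] + edges[mode_idx + 1]))
    return center, hist, len(sols)
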