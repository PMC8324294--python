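"""Synthetic single-particle-tracking data.

Generates ground-truth trajectories of a fluorescently tagged nuclear
protein switching between three diffusive states (immobile / slow / fast)
by a per-frame Markov chain, and renders them into camera movies with a
Gaussian PSF, Poisson shot noise and photobleaching.  Defaults follow a
HiLo live-cell acquisition: 32 ms frame interval, 100 nm pixels, 256x256
field of view, 2000 frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

STATE_NAMES = ("immobile", "slow", "fast")

__all__ = [
    "STATE_NAMES",
    "SPTSimParams",
    "GroundTruthTrack",
    "default_nucleus_mask",
    "stationary_distribution",
    "simulate_tracks",
    "render_spt_movie",
]


def default_nucleus_mask(fov: tuple[int, int] = (256, 256), radius_px: float | None = None) -> np.ndarray:
    """Binary disc mask centred in the field of view (a stand-in nucleus)."""
    h, w = fov
    if radius_px is None:
        radius_px = 0.4 * min(h, w)
    rr, cc = np.mgrid[0:h, 0:w]
    return (rr - (h - 1) / 2) ** 2 + (cc - (w - 1) / 2) ** 2 <= radius_px**2


def _sticky_transition_matrix(pi: np.ndarray, stay: float = 0.97) -> np.ndarray:
    """Transition matrix (1-a)*I + a*1*pi^T whose stationary law is ``pi``."""
    pi = np.asarray(pi, dtype=float)
    return stay * np.eye(len(pi)) + (1.0 - stay) * np.tile(pi, (len(pi), 1))


def stationary_distribution(transition_matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector).

    For a reducible matrix (e.g. the identity) the uniform distribution is
    returned.
    """
    T = np.asarray(transition_matrix, dtype=float)
    vals, vecs = np.linalg.eig(T.T)
    idx = np.argmin(np.abs(vals - 1.0))
    v = np.real(vecs[:, idx])
    if np.allclose(T, np.eye(T.shape[0])):
        return np.full(T.shape[0], 1.0 / T.shape[0])
    v = np.abs(v)
    return v / v.sum()


@dataclass
class SPTSimParams:
    """Parameters of the 3-state switching-diffusion movie generator.

    Diffusion coefficients are in um^2/s, lengths in um, times in seconds.
    ``transition_matrix`` holds per-frame state-switch probabilities;
    ``initial_state_probs`` defaults to its stationary distribution.
    ``loc_sigma`` is the localization error applied to reported positions
    (not to the dynamics); ``bleach_prob`` is the per-frame probability
    that a particle irreversibly disappears.
    """

    D_immobile: float = 0.003
    D_slow: float = 0.03
    D_fast: float = 1.5
    transition_matrix: np.ndarray = field(
        default_factory=lambda: _sticky_transition_matrix(np.array([0.34, 0.33, 0.33]))
    )
    initial_state_probs: np.ndarray | None = None
    frame_interval: float = 0.032
    n_frames: int = 2000
    pixel_size: float = 0.1
    fov: tuple[int, int] = (256, 256)
    loc_sigma: float = 0.03
    psf_sigma: float = 0.1
    photons_per_spot: float = 500.0
    background_photons: float = 10.0
    bleach_prob: float = 0.01
    n_particles: int = 50
    nucleus_mask: np.ndarray | None = None
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        D = np.array([self.D_immobile, self.D_slow, self.D_fast])
        if np.any(D < 0):
            raise ValueError("diffusion coefficients must be >= 0")
        if not (self.D_immobile < self.D_slow < self.D_fast):
            raise ValueError("require D_immobile < D_slow < D_fast")
        T = np.asarray(self.transition_matrix, dtype=float)
        if T.shape != (3, 3):
            raise ValueError("transition_matrix must be 3x3")
        if np.any(T < 0) or np.any(np.abs(T.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition_matrix rows must be probabilities summing to 1")
        self.transition_matrix = T
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.nucleus_mask is None:
            self.nucleus_mask = default_nucleus_mask(self.fov)
        self.nucleus_mask = np.asarray(self.nucleus_mask, dtype=bool)
        if self.nucleus_mask.shape != tuple(self.fov):
            raise ValueError("nucleus_mask shape must equal fov")

    @property
    def diffusion_coefficients(self) -> np.ndarray:
        return np.array([self.D_immobile, self.D_slow, self.D_fast])


@dataclass
class GroundTruthTrack:
    """One simulated trajectory with per-frame ground truth.

    ``x``/``y`` are true positions (um); ``x_obs``/``y_obs`` are the
    reported positions (true + localization error).  ``states`` indexes
    into :data:`STATE_NAMES`.  Records stop at the bleaching event.
    """

    track_id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    x_obs: np.ndarray
    y_obs: np.ndarray
    states: np.ndarray
    visible: np.ndarray

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def state_names(self) -> list[str]:
        return [STATE_NAMES[s] for s in self.states]


def _inside(mask: np.ndarray, x: float, y: float, pixel_size: float) -> bool:
    col = int(round(x / pixel_size))
    row = int(round(y / pixel_size))
    h, w = mask.shape
    return 0 <= row < h and 0 <= col < w and bool(mask[row, col])


class _MaskGeometry:
    """Signed distance field of the nucleus mask, for specular reflection."""

    def __init__(self, mask: np.ndarray, pixel_size: float) -> None:
        from scipy.ndimage import distance_transform_edt

        self.pixel_size = pixel_size
        inside = distance_transform_edt(mask)
        outside = distance_transform_edt(~mask)
        self.sdf = (inside - outside) * pixel_size  # um, > 0 inside
        self.gy, self.gx = np.gradient(self.sdf, pixel_size)
        self.h, self.w = mask.shape

    def _sample(self, field: np.ndarray, x: float, y: float) -> float:
        # bilinear sample in pixel units, clamped to the image
        c = min(max(x / self.pixel_size, 0.0), self.w - 1.001)
        r = min(max(y / self.pixel_size, 0.0), self.h - 1.001)
        c0, r0 = int(c), int(r)
        fc, fr = c - c0, r - r0
        return float(
            field[r0, c0] * (1 - fr) * (1 - fc)
            + field[r0, c0 + 1] * (1 - fr) * fc
            + field[r0 + 1, c0] * fr * (1 - fc)
            + field[r0 + 1, c0 + 1] * fr * fc
        )

    def dist(self, x: float, y: float) -> float:
        if not (0 <= x < self.w * self.pixel_size and 0 <= y < self.h * self.pixel_size):
            return -1.0
        return self._sample(self.sdf, x, y)

    def reflect(self, x0: float, y0: float, x1: float, y1: float) -> tuple[float, float]:
        """Specular reflection of the step (x0,y0)->(x1,y1) at the mask edge.

        The boundary crossing is located by bisection along the step and
        the remaining displacement is mirrored across the local tangent
        (normal from the distance-field gradient).  Falls back to staying
        put if the reflected point still leaves the mask after a few
        bounces (deep concavities).
        """
        px, py, qx, qy = x0, y0, x1, y1
        for _ in range(4):
            if self.dist(qx, qy) > 0:
                return qx, qy
            a, b = 0.0, 1.0
            for _ in range(14):
                m = 0.5 * (a + b)
                if self.dist(px + m * (qx - px), py + m * (qy - py)) > 0:
                    a = m
                else:
                    b = m
            cx, cy = px + a * (qx - px), py + a * (qy - py)
            nx, ny = self._sample(self.gx, cx, cy), self._sample(self.gy, cx, cy)
            norm = np.hypot(nx, ny)
            if norm < 1e-9:
                return x0, y0
            nx, ny = nx / norm, ny / norm
            rx, ry = qx - cx, qy - cy
            dot = rx * nx + ry * ny
            qx, qy = cx + rx - 2 * dot * nx, cy + ry - 2 * dot * ny
            px, py = cx, cy
        return (qx, qy) if self.dist(qx, qy) > 0 else (x0, y0)


def simulate_tracks(params: SPTSimParams) -> list[GroundTruthTrack]:
    """Simulate 3-state switching Brownian trajectories inside the nucleus.

    Each particle evolves by a Markov chain over mobility states with
    per-frame Gaussian displacements of variance ``2*D_state*dt`` per axis.
    Steps crossing the nuclear mask edge are specularly reflected at the
    boundary, which preserves uniform occupancy.  Reported positions add
    independent Gaussian localization error of sd ``loc_sigma``.
    """
    mask = params.nucleus_mask
    if not mask.any():
        raise ValueError("nucleus_mask has no interior pixels")
    geom = _MaskGeometry(mask, params.pixel_size)
    rng = np.random.default_rng([params.seed, 0])
    rows, cols = np.nonzero(mask)
    D = params.diffusion_coefficients
    step_sd = np.sqrt(2.0 * D * params.frame_interval)
    T = params.transition_matrix
    cum_T = np.cumsum(T, axis=1)
    p0 = params.initial_state_probs
    if p0 is None:
        p0 = stationary_distribution(T)
    p0 = np.asarray(p0, dtype=float)

    tracks: list[GroundTruthTrack] = []
    for tid in range(params.n_particles):
        # uniform start inside the mask (random interior pixel, jittered)
        i = rng.integers(len(rows))
        x = (cols[i] + rng.uniform(-0.5, 0.5)) * params.pixel_size
        y = (rows[i] + rng.uniform(-0.5, 0.5)) * params.pixel_size
        state = int(rng.choice(3, p=p0))
        # lifetime until bleaching (frame count of visibility)
        if params.bleach_prob > 0:
            life = 1 + int(rng.geometric(params.bleach_prob))
        else:
            life = params.n_frames
        n = min(life, params.n_frames)
        xs = np.empty(n)
        ys = np.empty(n)
        ss = np.empty(n, dtype=int)
        for f in range(n):
            xs[f], ys[f], ss[f] = x, y, state
            if f == n - 1:
                break
            sd = step_sd[state]
            dx, dy = rng.normal(0.0, sd, size=2) if sd > 0 else (0.0, 0.0)
            nx, ny = x + dx, y + dy
            if geom.dist(nx, ny) <= 0:
                nx, ny = geom.reflect(x, y, nx, ny)
            # enforce the pixel-mask definition of "inside" exactly
            if not _inside(mask, nx, ny, params.pixel_size):
                nx, ny = x, y
            x, y = nx, ny
            u = rng.uniform()
            state = int(np.searchsorted(cum_T[state], u))
        noise = rng.normal(0.0, params.loc_sigma, size=(n, 2)) if params.loc_sigma > 0 else np.zeros((n, 2))
        tracks.append(
            GroundTruthTrack(
                track_id=tid,
                frames=np.arange(n),
                x=xs,
                y=ys,
                x_obs=xs + noise[:, 0],
                y_obs=ys + noise[:, 1],
                states=ss,
                visible=np.ones(n, dtype=bool),
            )
        )
    return tracks


def _render_spot(image: np.ndarray, x_px: float, y_px: float, sigma_px: float, photons: float) -> None:
    """Add a pixel-integrated Gaussian spot (photon integral is exact)."""
    h, w = image.shape
    r = int(np.ceil(4 * sigma_px)) + 2
    r0, r1 = max(0, int(y_px) - r), min(h, int(y_px) + r + 1)
    c0, c1 = max(0, int(x_px) - r), min(w, int(x_px) + r + 1)
    if r0 >= r1 or c0 >= c1:
        return
    s = sigma_px * np.sqrt(2.0)
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    fy = 0.5 * (erf((rows + 0.5 - y_px) / s) - erf((rows - 0.5 - y_px) / s))
    fx = 0.5 * (erf((cols + 0.5 - x_px) / s) - erf((cols - 0.5 - x_px) / s))
    image[r0:r1, c0:c1] += photons * np.outer(fy, fx)


def render_spt_movie(tracks: list[GroundTruthTrack], params: SPTSimParams) -> np.ndarray:
    """Render trajectories into a (n_frames, H, W) photon-count movie.

    Each visible particle becomes a 2D Gaussian of width ``psf_sigma``
    integrated over pixels so the spot sums to ``photons_per_spot``; a
    constant background is added and, if ``shot_noise`` is set, Poisson
    noise is applied to the whole expected image.
    """
    h, w = params.fov
    rng = np.random.default_rng([params.seed, 1])
    sigma_px = params.psf_sigma / params.pixel_size
    by_frame: dict[int, list[tuple[float, float]]] = {}
    for tr in tracks:
        for f, xo, yo, vis in zip(tr.frames, tr.x_obs, tr.y_obs, tr.visible):
            if vis:
                by_frame.setdefault(int(f), []).append((xo / params.pixel_size, yo / params.pixel_size))
    movie = np.empty((params.n_frames, h, w))
    for f in range(params.n_frames):
        frame = np.full((h, w), float(params.background_photons))
        for x_px, y_px in by_frame.get(f, ()):
            _render_spot(frame, x_px, y_px, sigma_px, params.photons_per_spot)
        if params.shot_noise:
            frame = rng.poisson(frame).astype(float)
        movie[f] = frame
    return movie
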