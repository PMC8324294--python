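"""Mobility-state analysis of single-particle tracks.

Tracks are segmented into immobile / slow / fast tracklets with a
3-state Gaussian hidden Markov model on per-step log squared
displacements, decoded by the maximum-likelihood (Viterbi) state path.
The emission parameters are derived in closed form from the physics of
2D Brownian motion observed with localization error: for a state with
diffusion coefficient D, the squared step r^2 over one frame is
(2 D dt + 2 sigma_loc^2) * chi^2_2, so log r^2 is Gaussian-approximated
with mean log(2 D dt + 2 sigma_loc^2) + E[log chi^2_2] and variance
Var[log chi^2_2] = psi'(1).  No per-track EM fitting is performed; the
decoder is therefore deterministic.

Apparent diffusion coefficients are estimated from the slope of the
time-averaged MSD curve (ordinary least squares over the first 4 lags
with a free intercept that absorbs localization error; D = slope / 4),
for tracklets at least 10 frames long, and classified as immobile
(< 0.01 um^2/s, including values clipped at the D floor), slow
([0.01, 0.1)) or fast (>= 0.1).  Per-cell immobile fractions are the
percentage of classified tracklets that are immobile; conditions are
compared with a Welch two-sided t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM
from scipy import stats

STATE_NAMES = ("immobile", "slow", "fast")
_E_LOG_CHI2_2 = np.log(2.0) - np.euler_gamma  # E[log chi^2_2]
_VAR_LOG_CHI2_2 = np.pi**2 / 6.0  # psi'(1)

__all__ = [
    "Tracklet",
    "MSDCurve",
    "DiffusionEstimate",
    "MobilityClassBins",
    "CellMobilitySummary",
    "StateSegmenter",
    "segment_states",
    "compute_msd",
    "estimate_D",
    "classify_mobility",
    "cell_summary",
    "compare_conditions",
    "analyze_cell_tracks",
]


@dataclass
class Tracklet:
    """A contiguous single-state run of localizations within one track."""

    track_id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    state: str

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class MSDCurve:
    """Time-averaged mean squared displacement versus lag time."""

    lags: np.ndarray  # seconds
    msd: np.ndarray  # um^2
    n_pairs: np.ndarray


@dataclass
class DiffusionEstimate:
    """Apparent diffusion coefficient from an MSD slope fit."""

    D_app: float  # um^2/s
    intercept: float  # um^2
    n_lags: int


@dataclass
class MobilityClassBins:
    """Half-open D_app intervals for the three mobility classes.

    Sub-floor and sub-0.001 values map to immobile (negative fitted
    slopes are unphysical noise and the immobile histogram starts near
    1e-3 um^2/s).
    """

    immobile: tuple[float, float] = (0.001, 0.01)
    slow: tuple[float, float] = (0.01, 0.1)
    fast_min: float = 0.1
    D_floor: float = 1e-4

    def classify(self, D_app: float) -> str:
        if D_app < self.slow[0]:
            return "immobile"
        if D_app < self.slow[1]:
            return "slow"
        return "fast"


@dataclass
class CellMobilitySummary:
    """Per-cell tracklet counts per mobility class and immobile fraction (%)."""

    cell_id: str
    condition: str
    counts: dict[str, int]
    fractions: dict[str, float]  # percentages, sum to 100

    @property
    def immobile_fraction(self) -> float:
        return self.fractions["immobile"]


class StateSegmenter:
    """Fixed-parameter 3-state Gaussian HMM over log squared displacements.

    Parameters
    ----------
    frame_interval : seconds per frame.
    loc_sigma : localization error (um) entering the emission means.
    D_refs : class-representative diffusion coefficients (um^2/s); the
        defaults are the geometric centres of the immobile and slow
        intervals and the typical fast-state coefficient.
    p_stay : per-step self-transition probability (sticky prior).
    min_segment_length : decoded runs shorter than this many frames are
        merged into the neighbouring run with the closer emission mean.
    """

    def __init__(
        self,
        frame_interval: float = 0.032,
        loc_sigma: float = 0.03,
        D_refs: tuple[float, float, float] = (0.003, 0.03, 1.5),
        p_stay: float = 0.94,
        min_segment_length: int = 5,
    ) -> None:
        self.frame_interval = frame_interval
        self.loc_sigma = loc_sigma
        self.D_refs = tuple(D_refs)
        self.min_segment_length = min_segment_length
        means = np.log(2.0 * np.array(D_refs) * frame_interval + 2.0 * loc_sigma**2) + _E_LOG_CHI2_2
        order = np.argsort(means)  # states ordered by mean
        self.means_ = means[order]
        model = GaussianHMM(n_components=3, covariance_type="diag", init_params="", params="")
        model.startprob_ = np.full(3, 1.0 / 3.0)
        model.transmat_ = p_stay * np.eye(3) + (1.0 - p_stay) / 2.0 * (1.0 - np.eye(3))
        model.means_ = self.means_[:, None]
        model.covars_ = np.full((3, 1), _VAR_LOG_CHI2_2)
        model.n_features = 1
        self._model = model

    def decode(self, x: np.ndarray, y: np.ndarray, frames: np.ndarray) -> np.ndarray:
        """Viterbi state index per localization (length n)."""
        n = len(x)
        if n < 2:
            raise ValueError("track must have at least 2 localizations")
        dn = np.diff(np.asarray(frames, dtype=float))
        r2 = np.diff(x) ** 2 + np.diff(y) ** 2
        feats = np.log(r2 / dn + 1e-12)[:, None]
        _, path = self._model.decode(feats, algorithm="viterbi")
        path = self._merge_short_runs(path)
        # localization i inherits the state of step i; the last one that
        # of the final step, so tracklets partition the track
        return np.append(path, path[-1])

    def _merge_short_runs(self, path: np.ndarray) -> np.ndarray:
        path = path.copy()
        while True:
            runs = _runs(path)
            if len(runs) <= 1:
                return path
            lengths = [b - a for a, b, _ in runs]
            i = int(np.argmin(lengths))
            if lengths[i] >= self.min_segment_length:
                return path
            a, b, s = runs[i]
            left = runs[i - 1][2] if i > 0 else None
            right = runs[i + 1][2] if i < len(runs) - 1 else None
            if left is None:
                target = right
            elif right is None:
                target = left
            else:
                target = left if abs(self.means_[s] - self.means_[left]) <= abs(self.means_[s] - self.means_[right]) else right
            path[a:b] = target


def _runs(path: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs as (start, stop, state), stop exclusive."""
    breaks = np.flatnonzero(np.diff(path)) + 1
    bounds = np.concatenate([[0], breaks, [len(path)]])
    return [(int(a), int(b), int(path[a])) for a, b in zip(bounds[:-1], bounds[1:])]


def segment_states(
    x: np.ndarray,
    y: np.ndarray,
    frames: np.ndarray,
    segmenter: StateSegmenter | None = None,
    track_id: int = 0,
) -> list[Tracklet]:
    """Partition one track into single-state tracklets."""
    if segmenter is None:
        segmenter = StateSegmenter()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    frames = np.asarray(frames)
    states = segmenter.decode(x, y, frames)
    tracklets = []
    for a, b, s in _runs(states):
        tracklets.append(Tracklet(track_id=track_id, frames=frames[a:b], x=x[a:b], y=y[a:b], state=STATE_NAMES[s]))
    return tracklets


def compute_msd(tracklet: Tracklet | tuple, frame_interval: float = 0.032, n_lags_max: int | None = None) -> MSDCurve:
    """Time-averaged MSD over all localization pairs n frames apart.

    Pairs spanning gaps are honoured via the frame indices, so missing
    frames are simply excluded from the averaging.
    """
    if isinstance(tracklet, Tracklet):
        x, y, frames = tracklet.x, tracklet.y, tracklet.frames
    else:
        x, y, frames = tracklet
    if len(x) < 2:
        raise ValueError("tracklet must have at least 2 localizations")
    frames = np.asarray(frames, dtype=int)
    span = int(frames[-1] - frames[0])
    max_lag = min(n_lags_max, span) if n_lags_max is not None else span
    contiguous = span == len(frames) - 1
    pos = {int(f): i for i, f in enumerate(frames)}
    lags, msd, n_pairs = [], [], []
    for n in range(1, max_lag + 1):
        if contiguous:
            sq = (x[n:] - x[:-n]) ** 2 + (y[n:] - y[:-n]) ** 2
        else:
            sq = np.array(
                [
                    (x[pos[int(f) + n]] - x[i]) ** 2 + (y[pos[int(f) + n]] - y[i]) ** 2
                    for i, f in enumerate(frames)
                    if int(f) + n in pos
                ]
            )
        if sq.size:
            lags.append(n * frame_interval)
            msd.append(float(np.mean(sq)))
            n_pairs.append(len(sq))
    return MSDCurve(lags=np.array(lags), msd=np.array(msd), n_pairs=np.array(n_pairs))


def estimate_D(msd: MSDCurve, n_fit_lags: int = 4, D_floor: float = 1e-4) -> DiffusionEstimate:
    """Apparent D from an OLS fit of MSD on lag time (first 4 lags).

    D_app = slope / 4 with a free intercept absorbing localization error;
    negative slopes are clipped at the D floor.  Requires >= 2 lags.
    """
    n = min(n_fit_lags, len(msd.lags))
    if n < 2:
        raise ValueError("need at least 2 usable lags to fit")
    slope, intercept = np.polyfit(msd.lags[:n], msd.msd[:n], 1)
    return DiffusionEstimate(D_app=max(slope / 4.0, D_floor), intercept=float(intercept), n_lags=n)


def classify_mobility(estimate: DiffusionEstimate, bins: MobilityClassBins | None = None) -> str:
    """Mobility class of a diffusion estimate (half-open interval rule)."""
    if bins is None:
        bins = MobilityClassBins()
    return bins.classify(estimate.D_app)


def cell_summary(classes: list[str], cell_id: str = "", condition: str = "") -> CellMobilitySummary:
    """Per-class counts and percentages for the tracklets of one cell.

    The immobile fraction is count-weighted: 100 x immobile tracklets /
    classified tracklets.
    """
    if not classes:
        raise ValueError("no classified tracklets")
    counts = {s: int(sum(c == s for c in classes)) for s in STATE_NAMES}
    total = sum(counts.values())
    fractions = {s: 100.0 * counts[s] / total for s in STATE_NAMES}
    return CellMobilitySummary(cell_id=cell_id, condition=condition, counts=counts, fractions=fractions)


def compare_conditions(
    summaries_a: list[CellMobilitySummary] | np.ndarray,
    summaries_b: list[CellMobilitySummary] | np.ndarray,
    variance_floor: float = 1e-12,
) -> tuple[float, float, float, float]:
    """Welch two-sided t-test on per-cell immobile fractions.

    Returns (t statistic, two-sided p, median_a, median_b).  Variances
    are floored so zero-variance groups remain comparable; identical
    groups give t = 0, p = 1.
    """
    a = np.array([s.immobile_fraction if isinstance(s, CellMobilitySummary) else float(s) for s in summaries_a])
    b = np.array([s.immobile_fraction if isinstance(s, CellMobilitySummary) else float(s) for s in summaries_b])
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 cells")
    va = max(float(np.var(a, ddof=1)), variance_floor)
    vb = max(float(np.var(b, ddof=1)), variance_floor)
    se2a, se2b = va / len(a), vb / len(b)
    denom = np.sqrt(se2a + se2b)
    t = (float(np.mean(a)) - float(np.mean(b))) / denom
    df = (se2a + se2b) ** 2 / (se2a**2 / (len(a) - 1) + se2b**2 / (len(b) - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, float(p), float(np.median(a)), float(np.median(b))


def analyze_cell_tracks(
    tracks: list,
    frame_interval: float = 0.032,
    segmenter: StateSegmenter | None = None,
    bins: MobilityClassBins | None = None,
    min_tracklet_frames: int = 10,
    cell_id: str = "",
    condition: str = "",
) -> tuple[pd.DataFrame, CellMobilitySummary]:
    """Segment, estimate and classify all tracks of one cell.

    ``tracks`` are objects with ``frames``/``x``/``y`` arrays (observed
    positions when available) and a ``track_id``.  Tracklets shorter than
    ``min_tracklet_frames`` are excluded from the D analysis.  Returns a
    per-tracklet table and the cell summary.
    """
    if segmenter is None:
        segmenter = StateSegmenter(frame_interval=frame_interval)
    if bins is None:
        bins = MobilityClassBins()
    rows = []
    for tr in tracks:
        x = getattr(tr, "x_obs", None)
        x = tr.x if x is None else x
        y = getattr(tr, "y_obs", None)
        y = tr.y if y is None else y
        if len(tr.frames) < 2:
            continue
        for j, tl in enumerate(segment_states(x, y, tr.frames, segmenter, track_id=tr.track_id)):
            if len(tl) < min_tracklet_frames:
                continue
            est = estimate_D(compute_msd(tl, frame_interval, n_lags_max=4))
            rows.append(
                {
                    "cell_id": cell_id,
                    "condition": condition,
                    "track_id": tr.track_id,
                    "tracklet_id": j,
                    "n_frames": len(tl),
                    "hmm_state": tl.state,
                    "D_app": est.D_app,
                    "intercept": est.intercept,
                    "mobility_class": bins.classify(est.D_app),
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no tracklets long enough for D analysis")
    summary = cell_summary(list(table["mobility_class"]), cell_id=cell_id, condition=condition)
    return table, summary
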