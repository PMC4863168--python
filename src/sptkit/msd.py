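"""Time-averaged mean-square-displacement analysis and motion-model fitting.

For a 2D trajectory sampled at a fixed frame interval, the time-averaged
MSD at lag ``tau = k * dt`` is the average of the squared displacement over
all (overlapping) frame pairs separated by ``k`` frames.  Two motion models
are fitted to the curve:

* Brownian diffusion:   ``MSD(tau) = 4 D tau + eps``
* Flow (directed) motion: ``MSD(tau) = 4 D tau + (v tau)^2 + eps``

``D`` is the diffusion coefficient (um^2/s), ``v`` the drift speed
(reported in um/min), and ``eps >= 0`` a constant offset produced by the
localization uncertainty of the microscope.  Both models are linear in the
parameters ``(4D, v^2, eps)``, so the constrained fits are solved exactly
with nonnegative least squares; model selection uses an F-test on the
nested pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "Trajectory",
    "MSDCurve",
    "MotionFit",
    "TrackTooShortError",
    "compute_msd",
    "fit_brownian",
    "fit_flow",
    "select_model",
    "ensemble_msd",
]


class TrackTooShortError(ValueError):
    """Raised when a track has too few frames for the requested analysis."""


def _as_positions(positions) -> np.ndarray:
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 2:
        raise ValueError(f"positions must have shape (n, 2), got {pos.shape}")
    if not np.all(np.isfinite(pos)):
        raise ValueError("positions contain non-finite values")
    return pos


@dataclass(frozen=True)
class Trajectory:
    """One particle's time-ordered 2D positions.

    Parameters
    ----------
    track_id:
        Identifier of the track (string or int).
    positions:
        ``(n_frames, 2)`` array of (x, y) coordinates in micrometres, one
        row per frame, uniformly sampled.
    frame_interval:
        Time between consecutive frames, in seconds.
    """

    track_id: object
    positions: np.ndarray
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        pos = _as_positions(self.positions)
        object.__setattr__(self, "positions", pos)
        if pos.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def duration(self) -> float:
        """Total track time ``(n_frames - 1) * frame_interval`` in seconds."""
        return (self.n_frames - 1) * self.frame_interval


@dataclass(frozen=True)
class MSDCurve:
    """Time-averaged MSD values at an increasing grid of lags.

    ``lags`` are in seconds (integer multiples of the frame interval),
    ``values`` in um^2, and ``n_pairs[i]`` counts the frame pairs that were
    averaged at ``lags[i]``.
    """

    lags: np.ndarray
    values: np.ndarray
    n_pairs: np.ndarray
    max_lag_fraction: float = 0.1

    def __post_init__(self) -> None:
        object.__setattr__(self, "lags", np.asarray(self.lags, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "n_pairs", np.asarray(self.n_pairs, dtype=int))
        if not (len(self.lags) == len(self.values) == len(self.n_pairs)):
            raise ValueError("lags, values and n_pairs must have equal length")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("MSD values must be nonnegative")


@dataclass(frozen=True)
class MotionFit:
    """Result of fitting one motion model to an MSD curve.

    ``model`` is ``"brownian"`` or ``"flow"``; ``D`` in um^2/s, ``v`` in
    um/min (``None`` for the Brownian model), ``epsilon`` in um^2.  ``rss``
    is the residual sum of squares of the fit and ``p_value`` the F-test
    p-value of the nested comparison (set by :func:`select_model`).
    """

    model: str
    D: float
    epsilon: float
    v: float | None = None
    rss: float = 0.0
    n_lags: int = 0
    degenerate: bool = False
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.model not in ("brownian", "flow"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.D < 0 or self.epsilon < 0:
            raise ValueError("D and epsilon must be nonnegative")
        if self.model == "flow" and (self.v is None or self.v < 0):
            raise ValueError("flow model requires v >= 0")

    @property
    def v_um_per_s(self) -> float | None:
        return None if self.v is None else self.v / 60.0


def min_frames_for_msd(max_lag_fraction: float = 0.1) -> int:
    """Smallest track length with at least one admissible lag."""
    return int(np.ceil(1.0 / max_lag_fraction)) + 1


def compute_msd(track: Trajectory, max_lag_fraction: float = 0.1) -> MSDCurve:
    """Time-averaged MSD restricted to short lags.

    Long lags are averaged over few pairs and are statistically weak, so
    the curve is truncated at ``max_lag_fraction`` (default 10%) of the
    track length: admissible lags are ``k * dt`` for
    ``1 <= k <= floor(max_lag_fraction * n_frames)``.

    Raises
    ------
    TrackTooShortError
        If the track is shorter than :func:`min_frames_for_msd`.
    """
    if not 0 < max_lag_fraction <= 1:
        raise ValueError("max_lag_fraction must be in (0, 1]")
    n = track.n_frames
    min_n = min_frames_for_msd(max_lag_fraction)
    if n < min_n:
        raise TrackTooShortError(
            f"track {track.track_id!r} has {n} frames; at least {min_n} are "
            f"required for MSD analysis at max_lag_fraction={max_lag_fraction}"
        )
    max_k = int(np.floor(max_lag_fraction * n))
    pos = track.positions
    lags = np.arange(1, max_k + 1)
    values = np.empty(max_k)
    n_pairs = np.empty(max_k, dtype=int)
    for i, k in enumerate(lags):
        disp = pos[k:] - pos[:-k]
        values[i] = np.mean(np.sum(disp * disp, axis=1))
        n_pairs[i] = n - k
    return MSDCurve(
        lags=lags * track.frame_interval,
        values=values,
        n_pairs=n_pairs,
        max_lag_fraction=max_lag_fraction,
    )


def _nnls_fit(msd: MSDCurve, columns: list[np.ndarray], weighted: bool) -> tuple[np.ndarray, float]:
    """Nonnegative least squares on the given design columns.

    Returns the coefficient vector and the *unweighted* residual sum of
    squares (so Brownian/flow residuals are comparable regardless of the
    weighting choice used in the fit).
    """
    a = np.column_stack(columns)
    b = msd.values
    if weighted:
        w = np.sqrt(msd.n_pairs.astype(float))
        coef, _ = optimize.nnls(a * w[:, None], b * w)
    else:
        coef, _ = optimize.nnls(a, b)
    resid = b - a @ coef
    return coef, float(resid @ resid)


def fit_brownian(msd: MSDCurve, weighted: bool = False) -> MotionFit:
    """Fit ``MSD(tau) = 4 D tau + eps`` with ``D, eps >= 0``.

    ``weighted=True`` weights each lag by its pair count (rows scaled by
    ``sqrt(n_pairs)``), giving short lags more influence.
    """
    if len(msd.lags) < 2:
        raise ValueError("Brownian fit needs at least 2 lags")
    if np.all(msd.values == 0):
        return MotionFit("brownian", D=0.0, epsilon=0.0, rss=0.0,
                         n_lags=len(msd.lags), degenerate=True)
    tau = msd.lags
    coef, rss = _nnls_fit(msd, [4.0 * tau, np.ones_like(tau)], weighted)
    return MotionFit("brownian", D=coef[0], epsilon=coef[1], rss=rss,
                     n_lags=len(tau))


def fit_flow(msd: MSDCurve, weighted: bool = False) -> MotionFit:
    """Fit ``MSD(tau) = 4 D tau + v^2 tau^2 + eps`` with all parameters >= 0.

    The drift speed is reported in um/min (conversion factor 60 applied at
    this reporting boundary only).
    """
    if len(msd.lags) < 3:
        raise ValueError("flow fit needs at least 3 lags")
    if np.all(msd.values == 0):
        return MotionFit("flow", D=0.0, epsilon=0.0, v=0.0, rss=0.0,
                         n_lags=len(msd.lags), degenerate=True)
    tau = msd.lags
    coef, rss = _nnls_fit(msd, [4.0 * tau, tau**2, np.ones_like(tau)], weighted)
    v_um_per_min = float(np.sqrt(coef[1])) * 60.0
    return MotionFit("flow", D=coef[0], epsilon=coef[2], v=v_um_per_min,
                     rss=rss, n_lags=len(tau))


def select_model(msd: MSDCurve, alpha: float = 0.05, weighted: bool = False) -> MotionFit:
    """Choose between the Brownian and flow models for one MSD curve.

    The flow model nests the Brownian one (``v = 0``), so an F-test on the
    residual drop decides whether the quadratic term is warranted:
    ``F = (rss_b - rss_f) / (rss_f / (n - 3))`` with (1, n-3) degrees of
    freedom.  Flow is selected when ``p < alpha``; ties and degenerate
    curves fall back to Brownian (parsimony).
    """
    fb = fit_brownian(msd, weighted=weighted)
    ff = fit_flow(msd, weighted=weighted)
    n = len(msd.lags)
    if fb.degenerate or n <= 3 or ff.rss >= fb.rss:
        return MotionFit(**{**fb.__dict__, "p_value": 1.0})
    if ff.rss == 0:
        p = 0.0
    else:
        f_stat = (fb.rss - ff.rss) / (ff.rss / (n - 3))
        p = float(stats.f.sf(f_stat, 1, n - 3))
    chosen = ff if p < alpha else fb
    return MotionFit(**{**chosen.__dict__, "p_value": p})


def ensemble_msd(tracks: list[Trajectory], max_lag_fraction: float = 0.1) -> MSDCurve:
    """Pair-count-weighted mean MSD over an ensemble of tracks.

    All tracks must share one frame interval.  At each lag the per-track
    values are averaged with weights equal to their pair counts, which is
    identical to pooling all displacement pairs across tracks.
    """
    if not tracks:
        raise ValueError("ensemble_msd needs at least one track")
    dts = {t.frame_interval for t in tracks}
    if len(dts) != 1:
        raise ValueError(f"mixed frame intervals in ensemble: {sorted(dts)}")
    curves = [compute_msd(t, max_lag_fraction) for t in tracks]
    all_lags = np.unique(np.concatenate([c.lags for c in curves]))
    num = np.zeros(len(all_lags))
    den = np.zeros(len(all_lags), dtype=int)
    for c in curves:
        idx = np.searchsorted(all_lags, c.lags)
        num[idx] += c.values * c.n_pairs
        den[idx] += c.n_pairs
    return MSDCurve(lags=all_lags, values=num / den, n_pairs=den,
                    max_lag_fraction=max_lag_fraction)
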