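"""Two-channel colocalization: pixel-based Manders M1 and object-based overlap.

Quantifies how much of a "red" channel (e.g. labeled DNA cargo) overlaps
a "green" compartment channel (endosomes or lysosomes).  M1 is the
fraction of above-threshold red intensity falling inside the green mask
(M1 = colocalized red / total red); the object-based statistic counts
red spots whose centroid lies within a distance cutoff of any green spot
and reports the percentage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy import stats

__all__ = [
    "SpotSet",
    "ColocResult",
    "manders_m1",
    "costes_thresholds",
    "object_colocalization",
]


@dataclass(frozen=True)
class SpotSet:
    """Detected spots of one channel: centroids in um, optional radii."""

    channel: str
    centroids: np.ndarray
    radii: np.ndarray | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        if c.size and not np.all(np.isfinite(c)):
            raise ValueError("centroids contain non-finite values")
        object.__setattr__(self, "centroids", c)
        if self.radii is not None:
            r = np.asarray(self.radii, dtype=float)
            if np.any(r <= 0):
                raise ValueError("radii must be positive")
            object.__setattr__(self, "radii", r)

    def __len__(self) -> int:
        return self.centroids.shape[0]


@dataclass(frozen=True)
class ColocResult:
    """Colocalization statistics; ``m1`` / ``percent_colocalized`` are None
    when the corresponding mode was not computed or is undefined (no
    signal in the reference channel)."""

    m1: float | None = None
    percent_colocalized: float | None = None
    n_colocalized: int = 0
    n_total: int = 0
    max_dist: float | None = None
    red_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.m1 is not None and not 0.0 <= self.m1 <= 1.0:
            raise ValueError("M1 must lie in [0, 1]")
        if self.percent_colocalized is not None and not 0.0 <= self.percent_colocalized <= 100.0:
            raise ValueError("percent must lie in [0, 100]")
        if self.n_colocalized > self.n_total:
            raise ValueError("colocalized count cannot exceed total")


def manders_m1(red, green_mask, red_threshold: float = 0.0) -> ColocResult:
    """Manders M1: above-threshold red intensity inside the green mask over
    above-threshold red intensity everywhere.

    Pixels with ``red > red_threshold`` count as signal.  If no red pixel
    is above threshold, M1 is undefined and reported as None with zero
    counts.
    """
    red = np.asarray(red, dtype=float)
    mask = np.asarray(green_mask, dtype=bool)
    if red.shape != mask.shape:
        raise ValueError(f"image shapes differ: {red.shape} vs {mask.shape}")
    if red_threshold < 0:
        raise ValueError("red_threshold must be >= 0")
    signal = red > red_threshold
    total = float(red[signal].sum())
    if total == 0.0:
        return ColocResult(m1=None, n_colocalized=0, n_total=0,
                           red_threshold=red_threshold)
    inside = float(red[signal & mask].sum())
    return ColocResult(
        m1=inside / total,
        n_colocalized=int(np.count_nonzero(signal & mask)),
        n_total=int(np.count_nonzero(signal)),
        red_threshold=red_threshold,
    )


def costes_thresholds(red, green, n_steps: int = 256) -> tuple[float, float]:
    """Automatic Costes-style threshold pair for two intensity images.

    Regresses green on red (green ~ a*red + b), then walks the red
    threshold down from the maximum until the Pearson correlation of the
    pixels *below* the threshold pair drops to <= 0; returns
    (red_threshold, green_threshold = a*red_threshold + b).  Optional
    pre-step for :func:`manders_m1` when no manual threshold is known.
    """
    red = np.asarray(red, dtype=float).ravel()
    green = np.asarray(green, dtype=float).ravel()
    if red.shape != green.shape:
        raise ValueError("images must have the same size")
    slope, intercept, *_ = stats.linregress(red, green)
    for t in np.linspace(red.max(), red.min(), n_steps):
        below = (red < t) & (green < slope * t + intercept)
        if below.sum() < 3:
            continue
        if np.std(red[below]) == 0 or np.std(green[below]) == 0:
            continue
        r = np.corrcoef(red[below], green[below])[0, 1]
        if r <= 0:
            return float(t), float(slope * t + intercept)
    t = float(red.min())
    return t, float(slope * t + intercept)


def object_colocalization(red, green, max_dist: float = 0.5) -> ColocResult:
    """Object-based colocalization by centroid distance.

    A red spot counts as colocalized when its centroid lies within
    ``max_dist`` (um; default 0.5, roughly a diffraction-scale spot
    radius) of any green centroid.  Accepts :class:`SpotSet` objects or
    raw (n, 2) centroid arrays.  An empty red set yields an undefined
    percentage with zero counts; an empty green set yields 0%.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    red_c = red.centroids if isinstance(red, SpotSet) else np.asarray(red, dtype=float).reshape(-1, 2)
    green_c = green.centroids if isinstance(green, SpotSet) else np.asarray(green, dtype=float).reshape(-1, 2)
    n_red = red_c.shape[0]
    if n_red == 0:
        return ColocResult(percent_colocalized=None, n_colocalized=0,
                           n_total=0, max_dist=max_dist)
    if green_c.shape[0] == 0:
        return ColocResult(percent_colocalized=0.0, n_colocalized=0,
                           n_total=n_red, max_dist=max_dist)
    dists, _ = cKDTree(green_c).query(red_c, k=1)
    n_coloc = int(np.count_nonzero(dists <= max_dist))
    return ColocResult(
        percent_colocalized=100.0 * n_coloc / n_red,
        n_colocalized=n_coloc,
        n_total=n_red,
        max_dist=max_dist,
    )
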