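"""Synthetic 2D trajectory generator with known ground-truth motion structure.

Emulates intracellular vesicle tracks as recorded by live-cell confocal
single-particle tracking: positions in micrometres sampled at 1 frame/s
for 2-5 minutes, composed of alternating Brownian-diffusion domains
(D ~ 1e-4 to 1e-3 um^2/s) and directed "flow" domains (drift speeds
~0.3-0.45 um/min superposed on Brownian jitter), plus additive Gaussian
localization error on every stored position.  Ground-truth per-frame
domain labels are carried along so downstream classification can be
scored against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator

import numpy as np

from .msd import Trajectory

__all__ = [
    "MotionDomainSpec",
    "SimulatedTrack",
    "DEFAULT_FRAME_INTERVAL",
    "DEFAULT_NOISE_SD",
    "simulate_brownian",
    "simulate_stop_and_go",
    "iter_ensemble",
    "simulate_ensemble",
]

#: sampling interval of the emulated acquisitions, seconds (1 frame/s)
DEFAULT_FRAME_INTERVAL = 1.0

#: default localization-error s.d. in um.  The microscope's localization
#: uncertainty is not known for the emulated data, so this is a synthetic
#: convention: 0.02 um gives an MSD offset eps = 4 * sd^2 = 1.6e-3 um^2,
#: small against 4*D*tau = 4e-3 um^2 at tau = 1 s for D = 1e-3 um^2/s.
DEFAULT_NOISE_SD = 0.02

BROWNIAN = "brownian"
FLOW = "flow"


@dataclass(frozen=True)
class MotionDomainSpec:
    """One homogeneous stretch of motion within a track.

    ``kind`` is ``"brownian"`` or ``"flow"``; ``duration`` in frames;
    ``D`` in um^2/s applies to both kinds (flow superposes drift on
    diffusion); ``v`` (um/min) and ``heading`` (radians) apply to flow
    domains only.
    """

    kind: str
    duration: int
    D: float
    v: float = 0.0
    heading: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in (BROWNIAN, FLOW):
            raise ValueError(f"kind must be 'brownian' or 'flow', got {self.kind!r}")
        if self.duration < 1:
            raise ValueError("duration must be >= 1 frame")
        if self.D < 0:
            raise ValueError("D must be nonnegative")
        if self.kind == FLOW and self.v < 0:
            raise ValueError("flow speed v must be nonnegative")


@dataclass(frozen=True)
class SimulatedTrack:
    """Simulated positions plus the ground truth that generated them."""

    positions: np.ndarray            # (n, 2), um, localization noise included
    frame_interval: float            # s
    labels: np.ndarray               # (n,) per-frame ground-truth kind
    seed: int | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        labels = np.asarray(self.labels)
        if len(labels) != len(pos):
            raise ValueError("labels and positions must have equal length")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions contain non-finite values")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "labels", labels)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def to_trajectory(self, track_id: object = 0) -> Trajectory:
        return Trajectory(track_id=track_id, positions=self.positions,
                          frame_interval=self.frame_interval)


def simulate_stop_and_go(
    domains: list[MotionDomainSpec],
    dt: float = DEFAULT_FRAME_INTERVAL,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int | None = None,
    origin: tuple[float, float] = (0.0, 0.0),
) -> SimulatedTrack:
    """Concatenate motion domains into one stop-and-go track.

    The first frame sits at ``origin``; the increment leading into frame
    ``j`` uses the parameters of the domain that owns frame ``j``.  Each
    diffusive increment is Gaussian with per-axis variance ``2 D dt``;
    flow domains add the constant displacement ``v dt`` along their
    heading.  Localization noise of s.d. ``noise_sd`` is added to every
    stored position (measurement error; it does not accumulate into the
    true path).
    """
    if not domains:
        raise ValueError("at least one motion domain is required")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)

    durations = np.array([d.duration for d in domains])
    n = int(durations.sum())
    owner = np.repeat(np.arange(len(domains)), durations)   # domain of each frame
    labels = np.array([domains[i].kind for i in owner])

    # per-increment parameters: increment j-1 -> j uses domain of frame j
    inc_owner = owner[1:]
    sd = np.array([np.sqrt(2.0 * domains[i].D * dt) for i in inc_owner])
    drift = np.zeros((n - 1, 2))
    for i, d in enumerate(domains):
        if d.kind == FLOW:
            v_um_s = d.v / 60.0
            step = v_um_s * dt * np.array([np.cos(d.heading), np.sin(d.heading)])
            drift[inc_owner == i] = step

    increments = rng.standard_normal((n - 1, 2)) * sd[:, None] + drift
    true_path = np.vstack([np.array(origin), np.array(origin) + np.cumsum(increments, axis=0)])
    if noise_sd > 0:
        observed = true_path + rng.normal(0.0, noise_sd, size=(n, 2))
    else:
        observed = true_path
    return SimulatedTrack(positions=observed, frame_interval=dt,
                          labels=labels, seed=seed)


def simulate_brownian(
    D: float,
    n_frames: int,
    dt: float = DEFAULT_FRAME_INTERVAL,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int | None = None,
    origin: tuple[float, float] = (0.0, 0.0),
) -> SimulatedTrack:
    """Pure Brownian track: ``n_frames`` positions with per-axis increment
    variance ``2 D dt`` and localization noise on the stored positions."""
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    domain = MotionDomainSpec(kind=BROWNIAN, duration=n_frames, D=D)
    return simulate_stop_and_go([domain], dt=dt, noise_sd=noise_sd,
                                seed=seed, origin=origin)


def derive_track_seeds(seed: int | None, n_tracks: int) -> list[int]:
    """Deterministic per-track seeds spawned from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0]) for child in ss.spawn(n_tracks)]


def iter_ensemble(
    make_track: Callable[[int], SimulatedTrack],
    n_tracks: int,
    seed: int | None = None,
) -> Iterator[SimulatedTrack]:
    """Lazily yield ``n_tracks`` independent tracks.

    ``make_track(track_seed)`` builds one track from its derived seed;
    tracks are generated on demand so ensembles of 1e5 tracks never need
    to be resident simultaneously.
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    for track_seed in derive_track_seeds(seed, n_tracks):
        yield make_track(track_seed)


def simulate_ensemble(
    make_track: Callable[[int], SimulatedTrack],
    n_tracks: int,
    seed: int | None = None,
) -> list[SimulatedTrack]:
    """Materialized ensemble; see :func:`iter_ensemble` for the streaming form."""
    return list(iter_ensemble(make_track, n_tracks, seed=seed))


def make_stop_and_go_factory(
    D: float,
    v: float,
    flow_fraction: float,
    n_frames: int = 300,
    mean_flow_run: int = 20,
    dt: float = DEFAULT_FRAME_INTERVAL,
    noise_sd: float = DEFAULT_NOISE_SD,
    constant_heading: bool = True,
) -> Callable[[int], SimulatedTrack]:
    """Factory of stop-and-go tracks with a target flow-time fraction.

    Domains alternate between diffusion and flow; run lengths are drawn
    geometrically with mean ``mean_flow_run`` frames for flow and
    ``mean_flow_run * (1 - flow_fraction) / flow_fraction`` for diffusion,
    so the expected fraction of time in flow is ``flow_fraction``.
    ``constant_heading=True`` keeps one drift direction per track
    (transport along a single microtubule); otherwise each flow run draws
    a fresh heading.  ``flow_fraction = 0`` yields pure Brownian tracks.
    """
    if not 0 <= flow_fraction < 1:
        raise ValueError("flow_fraction must lie in [0, 1)")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")

    def make_track(seed: int) -> SimulatedTrack:
        if flow_fraction == 0:
            dom = [MotionDomainSpec(BROWNIAN, n_frames, D)]
            return simulate_stop_and_go(dom, dt=dt, noise_sd=noise_sd, seed=seed)
        # separate streams for domain structure and for the path itself
        seed_struct, seed_path = derive_track_seeds(seed, 2)
        rng = np.random.default_rng(seed_struct)
        mean_diff_run = mean_flow_run * (1 - flow_fraction) / flow_fraction
        track_heading = rng.uniform(0, 2 * np.pi)
        in_flow = bool(rng.random() < flow_fraction)
        domains: list[MotionDomainSpec] = []
        remaining = n_frames
        while remaining > 0:
            mean_run = mean_flow_run if in_flow else mean_diff_run
            dur = min(int(rng.geometric(1.0 / mean_run)), remaining)
            if in_flow:
                heading = track_heading if constant_heading else rng.uniform(0, 2 * np.pi)
                domains.append(MotionDomainSpec(FLOW, dur, D, v=v, heading=heading))
            else:
                domains.append(MotionDomainSpec(BROWNIAN, dur, D))
            remaining -= dur
            in_flow = not in_flow
        return simulate_stop_and_go(domains, dt=dt, noise_sd=noise_sd, seed=seed_path)

    return make_track
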