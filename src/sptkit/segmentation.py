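"""Rule-based segmentation of tracks into diffusion and flow-motion domains.

The algorithm mirrors stop-and-go transport analysis: (i) partition each
track into consecutive m-frame segments (m = 3 by default), (ii) average
the speed components v_x, v_y over each segment, (iii) derive ensemble
speed thresholds as 70% of the mean absolute components over all segments
of the ensemble and group consecutive segments into uniformly
above/below-threshold sequences, then (iv) classify an above-threshold
sequence of two or more segments as a flow-motion domain when its local
asphericity alpha_L exceeds a fixed threshold (0.8 by default, calibrated
against the Brownian false-positive rate).  Everything else is diffusion.

Speed thresholds are an ensemble property: the classification of one
track depends on the ensemble it is analyzed with, and outputs carry the
thresholds used for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .msd import Trajectory
from . import shape

__all__ = [
    "SegmentRecord",
    "SpeedThresholds",
    "SequenceRun",
    "Domain",
    "SegmentedTrack",
    "PopulationSummary",
    "partition_segments",
    "derive_thresholds",
    "group_sequences",
    "classify_domains",
    "segment_track",
    "segment_ensemble",
    "population_fractions",
]

DIFFUSION = "diffusion"
FLOW = "flow"


@dataclass(frozen=True)
class SegmentRecord:
    """One m-frame segment of a track with its mean speed components.

    ``start``/``stop`` are frame indices (stop exclusive); the terminal
    segment may be longer than m when the track length is not divisible
    by m (remainder frames are attached rather than dropped, so labels
    tile the track).  ``v_x``/``v_y`` are means of the per-frame
    displacement components within the span divided by dt (um/s);
    ``v_x_max``/``v_y_max`` are the per-frame maxima of the absolute
    components, kept for the alternative threshold statistic.
    """

    track_id: object
    start: int
    stop: int
    v_x: float
    v_y: float
    v_x_max: float
    v_y_max: float
    above_threshold: bool | None = None

    @property
    def n_frames(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True)
class SpeedThresholds:
    """Ensemble-derived speed thresholds with derivation metadata."""

    v_x_thr: float
    v_y_thr: float
    factor: float = 0.70
    statistic: str = "mean_abs"
    n_segments: int = 0

    def __post_init__(self) -> None:
        if self.v_x_thr < 0 or self.v_y_thr < 0:
            raise ValueError("thresholds must be nonnegative")


@dataclass(frozen=True)
class SequenceRun:
    """Maximal run of consecutive segments uniformly above or below threshold."""

    above: bool
    segments: tuple
    start: int
    stop: int

    @property
    def n_segments(self) -> int:
        return len(self.segments)


@dataclass(frozen=True)
class Domain:
    kind: str              # diffusion | flow
    start: int
    stop: int              # exclusive
    alpha_local: float
    degenerate: bool = False


@dataclass(frozen=True)
class SegmentedTrack:
    track_id: object
    labels: np.ndarray               # per-frame, diffusion | flow
    domains: tuple                   # of Domain, tiling the track
    thresholds: SpeedThresholds
    alpha_thr: float
    m: int

    @property
    def n_frames(self) -> int:
        return len(self.labels)

    @property
    def flow_time_fraction(self) -> float:
        return float(np.mean(self.labels == FLOW))

    @property
    def dominant_kind(self) -> str:
        # ties resolved toward diffusion (parsimony)
        return FLOW if self.flow_time_fraction > 0.5 else DIFFUSION


@dataclass(frozen=True)
class PopulationSummary:
    """Diffusion/flow composition of an ensemble, in two weightings.

    ``time_fractions`` weight every tracked frame equally; ``track_fractions``
    assign each track to its dominant-by-time kind and count tracks.
    """

    n_tracks: int
    n_frames_total: int
    time_fractions: dict
    track_fractions: dict


def partition_segments(track: Trajectory, m: int = 3) -> list[SegmentRecord]:
    """Split a track into consecutive non-overlapping m-frame segments.

    Requires at least ``2 m`` frames (the minimum for one candidate flow
    sequence of two segments).  Segment speeds are the means of the
    finite-difference velocities within the segment span.
    """
    if m < 2:
        raise ValueError("segment length m must be >= 2")
    n = track.n_frames
    if n < 2 * m:
        raise ValueError(
            f"track {track.track_id!r} has {n} frames; segmentation needs at least {2 * m}"
        )
    dt = track.frame_interval
    vel = np.diff(track.positions, axis=0) / dt     # (n-1, 2), um/s
    n_seg = n // m
    records = []
    for k in range(n_seg):
        start = k * m
        stop = (k + 1) * m if k < n_seg - 1 else n   # remainder joins last segment
        v = vel[start:stop - 1]
        records.append(SegmentRecord(
            track_id=track.track_id,
            start=start,
            stop=stop,
            v_x=float(v[:, 0].mean()),
            v_y=float(v[:, 1].mean()),
            v_x_max=float(np.abs(v[:, 0]).max()),
            v_y_max=float(np.abs(v[:, 1]).max()),
        ))
    return records


def derive_thresholds(
    segments: list[SegmentRecord],
    factor: float = 0.70,
    statistic: str = "mean_abs",
) -> SpeedThresholds:
    """Speed thresholds from the ensemble segment-speed distribution.

    ``statistic="mean_abs"`` (default): threshold = factor x mean of the
    absolute mean-speed components over all segments.  ``"mean_of_max"``
    uses the per-segment maxima of |v_x|, |v_y| instead — an alternative
    reading of "maximum values of the components"; both give one
    threshold pair per ensemble.
    """
    if not segments:
        raise ValueError("cannot derive thresholds from an empty segment list")
    if len(segments) < 10:
        raise ValueError("threshold derivation needs at least 10 segments")
    if statistic == "mean_abs":
        vx = np.array([abs(s.v_x) for s in segments])
        vy = np.array([abs(s.v_y) for s in segments])
    elif statistic == "mean_of_max":
        vx = np.array([s.v_x_max for s in segments])
        vy = np.array([s.v_y_max for s in segments])
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return SpeedThresholds(
        v_x_thr=float(factor * vx.mean()),
        v_y_thr=float(factor * vy.mean()),
        factor=factor,
        statistic=statistic,
        n_segments=len(segments),
    )


def _is_above(seg: SegmentRecord, thr: SpeedThresholds, rule: str) -> bool:
    ax, ay = abs(seg.v_x) >= thr.v_x_thr, abs(seg.v_y) >= thr.v_y_thr
    if rule == "or":
        return ax or ay
    if rule == "and":
        return ax and ay
    raise ValueError(f"unknown threshold rule {rule!r}")


def group_sequences(
    segments: list[SegmentRecord],
    thr: SpeedThresholds,
    rule: str = "or",
) -> list[SequenceRun]:
    """Group one track's segments into maximal uniform above/below runs.

    A segment is "above threshold" when |v_x| >= v_x_thr or |v_y| >=
    v_y_thr (default OR rule: a drift aligned with one axis must not be
    missed; AND available via ``rule``).
    """
    if not segments:
        return []
    flagged = [replace(s, above_threshold=_is_above(s, thr, rule)) for s in segments]
    runs = []
    run_start = 0
    for i in range(1, len(flagged) + 1):
        if i == len(flagged) or flagged[i].above_threshold != flagged[run_start].above_threshold:
            members = tuple(flagged[run_start:i])
            runs.append(SequenceRun(
                above=bool(members[0].above_threshold),
                segments=members,
                start=members[0].start,
                stop=members[-1].stop,
            ))
            run_start = i
    return runs


def classify_domains(
    sequences: list[SequenceRun],
    track: Trajectory,
    thr: SpeedThresholds,
    alpha_thr: float = 0.8,
    m: int = 3,
) -> SegmentedTrack:
    """Label every frame diffusion or flow from the grouped sequences.

    An above-threshold run of >= 2 segments becomes a flow-motion domain
    when the local asphericity alpha_L of its positions exceeds
    ``alpha_thr``; isolated above-threshold segments and runs failing the
    asphericity test are absorbed into diffusion.  Adjacent same-kind
    domains are merged and each final domain's alpha_L is computed on its
    merged span (degenerate spans — all positions identical — are labeled
    diffusion).
    """
    shape.thr_check(alpha_thr)
    n = track.n_frames
    if not sequences or sequences[0].start != 0 or sequences[-1].stop != n:
        raise ValueError("sequences must tile the track's frames")
    labels = np.full(n, DIFFUSION, dtype=object)
    for run in sequences:
        if run.above and run.n_segments >= 2:
            g = shape.gyration_tensor(track.positions[run.start:run.stop])
            if not g.degenerate and g.asphericity > alpha_thr:
                labels[run.start:run.stop] = FLOW
    labels = labels.astype(str)

    domains = []
    start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            span = track.positions[start:i]
            if i - start >= 2:
                g = shape.gyration_tensor(span)
                alpha_local, degen = g.asphericity, g.degenerate
            else:
                alpha_local, degen = 0.0, True
            domains.append(Domain(kind=str(labels[start]), start=start, stop=i,
                                  alpha_local=alpha_local, degenerate=degen))
            start = i
    return SegmentedTrack(track_id=track.track_id, labels=labels,
                          domains=tuple(domains), thresholds=thr,
                          alpha_thr=alpha_thr, m=m)


def segment_track(
    track: Trajectory,
    thr: SpeedThresholds,
    m: int = 3,
    alpha_thr: float = 0.8,
    rule: str = "or",
) -> SegmentedTrack:
    """Partition, group and classify one track against given thresholds."""
    segments = partition_segments(track, m=m)
    sequences = group_sequences(segments, thr, rule=rule)
    return classify_domains(sequences, track, thr, alpha_thr=alpha_thr, m=m)


def segment_ensemble(
    tracks: list[Trajectory],
    m: int = 3,
    factor: float = 0.70,
    alpha_thr: float = 0.8,
    rule: str = "or",
    statistic: str = "mean_abs",
) -> tuple[list[SegmentedTrack], SpeedThresholds]:
    """Segment a whole ensemble with thresholds derived from that ensemble."""
    all_segments = []
    per_track = []
    for t in tracks:
        segs = partition_segments(t, m=m)
        per_track.append(segs)
        all_segments.extend(segs)
    thr = derive_thresholds(all_segments, factor=factor, statistic=statistic)
    out = []
    for t, segs in zip(tracks, per_track):
        sequences = group_sequences(segs, thr, rule=rule)
        out.append(classify_domains(sequences, t, thr, alpha_thr=alpha_thr, m=m))
    return out, thr


def population_fractions(segmented: list[SegmentedTrack]) -> PopulationSummary:
    """Diffusion/flow fractions of an ensemble, time- and track-weighted."""
    if not segmented:
        raise ValueError("population_fractions needs at least one segmented track")
    n_flow_frames = sum(int(np.sum(s.labels == FLOW)) for s in segmented)
    n_total = sum(s.n_frames for s in segmented)
    n_flow_tracks = sum(1 for s in segmented if s.dominant_kind == FLOW)
    time_flow = n_flow_frames / n_total
    track_flow = n_flow_tracks / len(segmented)
    return PopulationSummary(
        n_tracks=len(segmented),
        n_frames_total=n_total,
        time_fractions={DIFFUSION: 1.0 - time_flow, FLOW: time_flow},
        track_fractions={DIFFUSION: 1.0 - track_flow, FLOW: track_flow},
    )
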