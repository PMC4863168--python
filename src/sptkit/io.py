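"""Trajectory table readers/writers and the end-to-end pipeline.

Tracks travel as delimited text with columns ``track_id, frame, x_um,
y_um[, label]`` (the "plain" dialect) or as TrackMate spot exports
(``TRACK_ID, FRAME, POSITION_X, POSITION_Y``, with the extra non-numeric
header rows of newer TrackMate versions tolerated).  Coordinates are
real-valued micrometres, frames 0-based integers; output files start
with ``#`` comment lines carrying the config hash and master seed so any
run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .msd import Trajectory, TrackTooShortError, compute_msd, select_model, min_frames_for_msd
from .segmentation import segment_ensemble, population_fractions
from .shape import AsphericityCalibration, calibrate_tail_probability
from .synthetic import SimulatedTrack, make_stop_and_go_factory, iter_ensemble

__all__ = [
    "ParseError",
    "read_tracks",
    "write_tracks",
    "write_segmented",
    "write_msd_curve",
    "run_pipeline",
    "PAPER_LIKE_CONDITIONS",
]

logger = logging.getLogger("sptkit")

PLAIN_COLUMNS = {"track_id": "track_id", "frame": "frame", "x": "x_um", "y": "y_um"}
TRACKMATE_COLUMNS = {"track_id": "TRACK_ID", "frame": "FRAME",
                     "x": "POSITION_X", "y": "POSITION_Y"}


class ParseError(ValueError):
    """Malformed trajectory table (missing columns, duplicate frames...)."""


def _resolve_columns(df: pd.DataFrame, dialect: str) -> dict:
    lower = {c.lower(): c for c in df.columns}
    candidates = []
    if dialect in ("plain", "auto"):
        candidates.append(PLAIN_COLUMNS)
    if dialect in ("trackmate", "auto"):
        candidates.append(TRACKMATE_COLUMNS)
    for mapping in candidates:
        resolved = {k: lower.get(v.lower()) for k, v in mapping.items()}
        if all(resolved.values()):
            return resolved
    raise ParseError(
        f"could not resolve required columns for dialect {dialect!r}; "
        f"file has columns {list(df.columns)}"
    )


def _split_at_gaps(track_id, frames, xy, policy: str):
    """Yield (sub_id, positions) pieces according to the gap policy.

    ``split`` cuts the track at every missing frame; ``bridge``
    interpolates gaps of a single missing frame and cuts at larger ones.
    """
    steps = np.diff(frames)
    if np.any(steps > 1):
        logger.warning("track %r has %d frame gap(s)",
                       track_id, int(np.count_nonzero(steps > 1)))
    split_over = 2 if policy == "bridge" else 1
    cuts = np.flatnonzero(steps > split_over)
    bounds = [0, *(cuts + 1), len(frames)]
    multi = len(bounds) > 2
    for piece, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
        f, p = frames[lo:hi], xy[lo:hi]
        if policy == "bridge" and f[-1] - f[0] + 1 > len(f):
            full = np.arange(f[0], f[-1] + 1)
            p = np.column_stack([np.interp(full, f, p[:, 0]),
                                 np.interp(full, f, p[:, 1])])
        yield (f"{track_id}.{piece}" if multi else track_id), p


def read_tracks(
    path,
    dialect: str = "auto",
    frame_interval: float = 1.0,
    gap_policy: str = "split",
    min_frames: int = 2,
) -> list[Trajectory]:
    """Read a delimited trajectory table into :class:`Trajectory` objects.

    Tracks are sorted by frame; duplicate (track, frame) pairs raise a
    :class:`ParseError` naming the offending rows; tracks with missing
    frames are split at the gaps (default) or bridged by interpolating
    single missing frames (``gap_policy="bridge"``).  Pieces shorter than
    ``min_frames`` are dropped.  An empty file returns an empty list with
    a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    import csv as _csv
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except (pd.errors.EmptyDataError, _csv.Error):
        warnings.warn(f"{path}: empty trajectory file", stacklevel=2)
        return []
    if df.empty:
        warnings.warn(f"{path}: no data rows", stacklevel=2)
        return []
    cols = _resolve_columns(df, dialect)
    sub = df[[cols["track_id"], cols["frame"], cols["x"], cols["y"]]].copy()
    sub.columns = ["track_id", "frame", "x", "y"]
    # TrackMate >= 7 ships three extra header rows with units; drop rows
    # whose frame is not numeric.
    numeric_frame = pd.to_numeric(sub["frame"], errors="coerce")
    sub = sub[numeric_frame.notna()].copy()
    if sub.empty:
        warnings.warn(f"{path}: no numeric data rows", stacklevel=2)
        return []
    sub["frame"] = numeric_frame[numeric_frame.notna()].astype(int)
    sub["x"] = pd.to_numeric(sub["x"])
    sub["y"] = pd.to_numeric(sub["y"])

    dup = sub.duplicated(subset=["track_id", "frame"], keep=False)
    if dup.any():
        rows = (sub.index[dup] + 2).tolist()[:10]  # 1-based incl. header
        raise ParseError(f"duplicate (track_id, frame) pairs at file rows {rows}")

    tracks: list[Trajectory] = []
    for track_id, grp in sub.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy()
        xy = grp[["x", "y"]].to_numpy(dtype=float)
        for sub_id, piece in _split_at_gaps(track_id, frames, xy, gap_policy):
            if len(piece) >= max(min_frames, 2):
                tracks.append(Trajectory(track_id=sub_id, positions=piece,
                                         frame_interval=frame_interval))
    return tracks


def _header_lines(config: AnalysisConfig | None, seed=None, extra=()) -> str:
    lines = []
    if config is not None:
        lines.append(f"# config_hash: {config.config_hash()}")
    if seed is not None:
        lines.append(f"# seed: {seed}")
    lines += [f"# {e}" for e in extra]
    lines.append("# units: positions um, time s")
    return "\n".join(lines) + "\n"


def write_tracks(tracks, path, labels=None, config: AnalysisConfig | None = None,
                 seed=None) -> None:
    """Write tracks (Trajectory or SimulatedTrack) to the plain dialect."""
    rows = []
    for i, t in enumerate(tracks):
        if isinstance(t, SimulatedTrack):
            tid, pos, lab = i, t.positions, t.labels
        else:
            tid, pos = t.track_id, t.positions
            lab = labels[i] if labels is not None else None
        for f in range(len(pos)):
            row = {"track_id": tid, "frame": f,
                   "x_um": pos[f, 0], "y_um": pos[f, 1]}
            if lab is not None:
                row["label"] = lab[f]
            rows.append(row)
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(_header_lines(config, seed))
        df.to_csv(fh, index=False)


def write_msd_curve(curve, path, config=None, seed=None) -> None:
    df = pd.DataFrame({"lag_s": curve.lags, "msd_um2": curve.values,
                       "n_pairs": curve.n_pairs})
    with open(path, "w") as fh:
        fh.write(_header_lines(config, seed))
        df.to_csv(fh, index=False)


def write_segmented(segmented, tracks, path, config=None, seed=None) -> None:
    """Per-frame segmentation table: track_id, frame, x, y, label, domain_id, alpha_L."""
    rows = []
    for seg, track in zip(segmented, tracks):
        domain_of_frame = np.empty(seg.n_frames, dtype=int)
        alpha_of_frame = np.empty(seg.n_frames)
        for di, dom in enumerate(seg.domains):
            domain_of_frame[dom.start:dom.stop] = di
            alpha_of_frame[dom.start:dom.stop] = dom.alpha_local
        for f in range(seg.n_frames):
            rows.append({
                "track_id": seg.track_id, "frame": f,
                "x_um": track.positions[f, 0], "y_um": track.positions[f, 1],
                "label": seg.labels[f], "domain_id": domain_of_frame[f],
                "alpha_L": alpha_of_frame[f],
            })
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(_header_lines(config, seed))
        df.to_csv(fh, index=False)


#: two-condition demo regimes: a diffusion-dominant formulation (higher D,
#: little active transport) vs. a flow-dominant one (lower D, mostly
#: microtubule transport), both at the experimentally observed parameter
#: magnitudes D ~ 1e-3 / 3.7e-4 um^2/s and v ~ 0.45 um/min.
PAPER_LIKE_CONDITIONS = {
    "LFN-like": {"D": 1.0e-3, "v": 0.45, "flow_fraction": 0.25, "n_tracks": 60},
    "DD-like": {"D": 3.7e-4, "v": 0.45, "flow_fraction": 0.70, "n_tracks": 60},
}


def _condition_tracks(name: str, cond: dict, config: AnalysisConfig, seed: int):
    factory = make_stop_and_go_factory(
        D=cond["D"], v=cond["v"], flow_fraction=cond["flow_fraction"],
        n_frames=int(cond.get("n_frames", 300)),
        mean_flow_run=int(cond.get("mean_flow_run", 20)),
        dt=config.frame_interval,
        noise_sd=float(cond.get("noise_sd", 0.02)),
    )
    sims = list(iter_ensemble(factory, int(cond["n_tracks"]), seed=seed))
    tracks = [s.to_trajectory(f"{name}-{i}") for i, s in enumerate(sims)]
    return sims, tracks


def run_pipeline(
    config: AnalysisConfig,
    out_dir,
    input_path=None,
    conditions: dict | None = None,
) -> dict:
    """Run simulate/ingest -> MSD fits -> calibration -> segmentation ->
    population summary, writing every intermediate table under ``out_dir``.

    Exactly one of ``input_path`` (a trajectory table, analyzed as one
    condition) or ``conditions`` (mapping name -> simulation parameters
    ``{D, v, flow_fraction, n_tracks[, n_frames, mean_flow_run,
    noise_sd]}``) must be given.  Runs with identical config and inputs
    produce byte-identical outputs.
    """
    if (input_path is None) == (conditions is None):
        raise ValueError("provide exactly one of input_path or conditions")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    # Brownian false-positive calibration, cached on disk
    calib_path = out / "calibration.json"
    calibration = None
    if calib_path.exists():
        cached = AsphericityCalibration.load(calib_path)
        if (cached.n_sims == config.calibration_n_sims
                and cached.alpha_thr == config.alpha_thr
                and cached.seed == seed
                and tuple(cached.track_lengths) == config.calibration_lengths):
            calibration = cached
            logger.info("reusing cached calibration %s", calib_path)
    if calibration is None:
        calibration = calibrate_tail_probability(
            track_lengths=config.calibration_lengths,
            alpha_thr=config.alpha_thr,
            n_sims=config.calibration_n_sims,
            seed=seed,
        )
        calibration.save(calib_path)

    if input_path is not None:
        cond_tracks = {"input": read_tracks(
            input_path, frame_interval=config.frame_interval,
            gap_policy=config.gap_policy)}
    else:
        cond_tracks = {}
        for i, (name, cond) in enumerate(sorted(conditions.items())):
            _, tracks = _condition_tracks(name, cond, config, seed + i + 1)
            cond_tracks[name] = tracks

    fit_rows, pop_rows = [], []
    report: dict = {"config_hash": config.config_hash(), "seed": seed,
                    "calibration": {str(k): v for k, v in
                                    calibration.tail_probabilities.items()},
                    "conditions": {}}
    for name, tracks in cond_tracks.items():
        if not tracks:
            raise ValueError(f"condition {name!r} produced no tracks")
        logger.info("condition %s: %d tracks", name, len(tracks))
        write_tracks(tracks, out / f"tracks_{name}.csv", config=config, seed=seed)

        usable = [t for t in tracks
                  if t.n_frames >= min_frames_for_msd(config.max_lag_fraction)]
        for t in usable:
            curve = compute_msd(t, config.max_lag_fraction)
            fit = select_model(curve, alpha=config.model_selection_alpha,
                               weighted=config.fit_weighted)
            fit_rows.append({"condition": name, "track_id": t.track_id,
                             "n_frames": t.n_frames, "model": fit.model,
                             "D_um2_s": fit.D, "v_um_min": fit.v,
                             "epsilon_um2": fit.epsilon, "p_value": fit.p_value})

        seg_ok = [t for t in tracks if t.n_frames >= 2 * config.m]
        segmented, thr = segment_ensemble(
            seg_ok, m=config.m, factor=config.speed_threshold_factor,
            alpha_thr=config.alpha_thr, rule=config.threshold_rule,
            statistic=config.threshold_statistic)
        write_segmented(segmented, seg_ok, out / f"segmented_{name}.csv",
                        config=config, seed=seed)
        summary = population_fractions(segmented)
        row = {"condition": name, "n_tracks": summary.n_tracks,
               "v_x_thr": thr.v_x_thr, "v_y_thr": thr.v_y_thr}
        if config.weighting in ("time", "both"):
            row["time_diffusion"] = summary.time_fractions["diffusion"]
            row["time_flow"] = summary.time_fractions["flow"]
        if config.weighting in ("tracks", "both"):
            row["tracks_diffusion"] = summary.track_fractions["diffusion"]
            row["tracks_flow"] = summary.track_fractions["flow"]
        pop_rows.append(row)
        report["conditions"][name] = row

    with open(out / "msd_fits.csv", "w") as fh:
        fh.write(_header_lines(config, seed))
        pd.DataFrame(fit_rows).to_csv(fh, index=False)
    with open(out / "population.csv", "w") as fh:
        fh.write(_header_lines(config, seed))
        pd.DataFrame(pop_rows).to_csv(fh, index=False)
    config.to_yaml(out / "config.yaml")
    return report
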