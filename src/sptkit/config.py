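"""Analysis configuration: every tunable of the pipeline in one
serializable, hashable record."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field, replace
from pathlib import Path

import yaml

from .shape import DEFAULT_CALIBRATION_LENGTHS

__all__ = ["AnalysisConfig"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline parameters.

    Units: positions um, time s; drift speeds are reported in um/min.
    ``max_lag_fraction`` truncates MSD curves (default 10% of track
    length); ``m`` is the segment length in frames; the speed thresholds
    are ``speed_threshold_factor`` x the ensemble mean absolute segment
    speeds; ``alpha_thr`` is the local-asphericity cut for flow domains.
    """

    frame_interval: float = 1.0          # s
    max_lag_fraction: float = 0.1
    m: int = 3                           # frames per segment
    speed_threshold_factor: float = 0.70
    alpha_thr: float = 0.8
    threshold_rule: str = "or"           # or | and
    threshold_statistic: str = "mean_abs"  # mean_abs | mean_of_max
    fit_weighted: bool = False           # weight MSD fits by pair counts
    model_selection_alpha: float = 0.05
    calibration_n_sims: int = 10_000
    calibration_lengths: tuple = DEFAULT_CALIBRATION_LENGTHS
    seed: int = 0
    position_unit: str = "um"
    time_unit: str = "s"
    weighting: str = "both"              # time | tracks | both
    gap_policy: str = "split"            # split | bridge

    def __post_init__(self) -> None:
        if not 0 < self.max_lag_fraction <= 1:
            raise ValueError("max_lag_fraction must be in (0, 1]")
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if not 0 < self.speed_threshold_factor:
            raise ValueError("speed_threshold_factor must be positive")
        if not 0 <= self.alpha_thr <= 1:
            raise ValueError("alpha_thr must be in [0, 1]")
        if self.threshold_rule not in ("or", "and"):
            raise ValueError("threshold_rule must be 'or' or 'and'")
        if self.threshold_statistic not in ("mean_abs", "mean_of_max"):
            raise ValueError("unknown threshold_statistic")
        if self.weighting not in ("time", "tracks", "both"):
            raise ValueError("weighting must be 'time', 'tracks' or 'both'")
        if self.gap_policy not in ("split", "bridge"):
            raise ValueError("gap_policy must be 'split' or 'bridge'")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        object.__setattr__(self, "calibration_lengths",
                           tuple(int(n) for n in self.calibration_lengths))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["calibration_lengths"] = list(self.calibration_lengths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Short stable digest embedded in every output for provenance."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def replace(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)
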