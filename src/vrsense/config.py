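"""Pipeline configuration: every named constant in one validated place.

Defaults follow the reference protocol: 0.1 m grid cells, 0.2 m/s moving
threshold, 5-s windows, 6 stress levels, class bands cut at 0.33/0.66,
subject classification cut at 0.3/0.6, equal-weight fusion, 4 screenshot
directions, top-5 hotspots.  A YAML file can override any field, and every
CLI run writes an effective-config snapshot next to its outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

from .errors import FormatError, ValidationError


@dataclass(frozen=True)
class PipelineConfig:
    cell_size: float = 0.1  # m
    speed_threshold: float = 0.2  # m/s
    window_s: float = 5.0  # s
    n_states: int = 6
    class_thresholds: tuple[float, float] = (0.33, 0.66)  # score -> 3-level class
    classify_cuts: tuple[float, float] = (0.3, 0.6)  # subject banding
    fusion_weight: float = 0.5
    n_directions: int = 4
    top_k: int = 5
    seed: int = 0
    n_init: int = 10
    moving_time_stat: str = "sum"  # or "mean"
    hotspot_centre: str = "mode_cell"  # or "mean_cell"
    decode_mode: str = "viterbi"  # or "posterior"
    stress_score_mode: str = "expected_level"  # or "mode_level"

    def __post_init__(self) -> None:
        positive = {
            "cell_size": self.cell_size,
            "speed_threshold": self.speed_threshold,
            "window_s": self.window_s,
            "n_states": self.n_states,
            "n_directions": self.n_directions,
            "top_k": self.top_k,
            "n_init": self.n_init,
        }
        for name, v in positive.items():
            if v <= 0:
                raise ValidationError(f"config: {name} must be positive, got {v!r}")
        for name, pair in (
            ("class_thresholds", self.class_thresholds),
            ("classify_cuts", self.classify_cuts),
        ):
            lo, hi = pair
            if not 0.0 < lo < hi <= 1.0:
                raise ValidationError(
                    f"config: {name} must satisfy 0 < lo < hi <= 1, got {pair!r}"
                )
        if not 0.0 <= self.fusion_weight <= 1.0:
            raise ValidationError(
                f"config: fusion_weight must be in [0, 1], got {self.fusion_weight!r}"
            )
        for name, v, allowed in (
            ("moving_time_stat", self.moving_time_stat, {"sum", "mean"}),
            ("hotspot_centre", self.hotspot_centre, {"mode_cell", "mean_cell"}),
            ("decode_mode", self.decode_mode, {"viterbi", "posterior"}),
            ("stress_score_mode", self.stress_score_mode,
             {"expected_level", "mode_level"}),
        ):
            if v not in allowed:
                raise ValidationError(
                    f"config: {name} must be one of {sorted(allowed)}, got {v!r}"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["class_thresholds"] = list(self.class_thresholds)
        d["classify_cuts"] = list(self.classify_cuts)
        return d

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        for key in ("class_thresholds", "classify_cuts"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise FormatError(f"{path}: config must be a mapping")
        known = set(cls().to_dict())
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls().with_overrides(**raw)

    def snapshot(self, out_dir) -> Path:
        """Write the effective configuration next to a run's outputs."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "effective_config.json"
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        return path
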