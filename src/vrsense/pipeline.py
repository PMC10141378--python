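"""End-to-end session assessment: trajectories + labels -> report bundle.

Ties the stages together the way the CLI and tests consume them: windowed
feature extraction per subject, one global stress HMM fitted over all
subjects' sequences, per-subject decoding and stress scoring, session
hotspot ranking, per-hotspot visual scores, fusion and reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .config import PipelineConfig
from .errors import ValidationError
from .features import FeatureVector, features_frame, window_features
from .fusion import ReportBundle, assess_hotspots, build_report
from .hotspots import HotspotRecord, hotspots_frame, top_hotspots, visit_table
from .sentiment import ScreenshotLabel
from .stress import StressHMM, decode_stress, fit_hmm, stress_score
from .trajectory import Trajectory

logger = logging.getLogger(__name__)


@dataclass
class SessionResult:
    """Everything a full pipeline run produced, in memory plus on disk."""

    features: dict[str, list[FeatureVector]]
    hotspots: dict[str, list[HotspotRecord]]
    model: StressHMM
    stress_scores: dict[str, float]
    assessments: pd.DataFrame
    report: ReportBundle


def extract_features(
    trajectories: Mapping[str, Trajectory], config: PipelineConfig
) -> dict[str, list[FeatureVector]]:
    out = {}
    for sid, traj in sorted(trajectories.items()):
        out[sid] = window_features(
            traj,
            window=config.window_s,
            speed_threshold=config.speed_threshold,
            cell_size=config.cell_size,
            moving_time_stat=config.moving_time_stat,
            hotspot_centre=config.hotspot_centre,
        )
    return out


def rank_hotspots(
    trajectories: Mapping[str, Trajectory], config: PipelineConfig
) -> dict[str, list[HotspotRecord]]:
    return {
        sid: top_hotspots(
            visit_table(traj, config.cell_size), config.top_k, config.n_directions
        )
        for sid, traj in sorted(trajectories.items())
    }


def score_stress(
    features: Mapping[str, Sequence[FeatureVector]],
    config: PipelineConfig,
    model: StressHMM | None = None,
) -> tuple[StressHMM, dict[str, float]]:
    """Fit (or reuse) the global stress model and score each subject."""
    sequences = {sid: fvs for sid, fvs in features.items() if len(fvs) >= 1}
    if not sequences:
        raise ValidationError("score_stress: no subject has any feature windows")
    if model is None:
        model = fit_hmm(
            list(sequences.values()), seed=config.seed, n_init=config.n_init
        )
    scores = {}
    for sid, fvs in sorted(sequences.items()):
        trace = decode_stress(model, fvs, mode=config.decode_mode)
        scores[sid] = stress_score(trace, mode=config.stress_score_mode)
    return model, scores


def run_session(
    trajectories: Mapping[str, Trajectory],
    labels: Sequence[ScreenshotLabel],
    config: PipelineConfig,
    out_dir,
    model: StressHMM | None = None,
    plots: bool = False,
) -> SessionResult:
    """Run the whole assessment and write the report bundle to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    features = extract_features(trajectories, config)
    features_frame(features).to_csv(out_dir / "features.csv", index=False)

    hotspots = rank_hotspots(trajectories, config)
    hotspots_frame(hotspots).to_csv(out_dir / "hotspots.csv", index=False)

    model, scores = score_stress(features, config, model)
    model.to_json(out_dir / "stress_model.json")
    pd.DataFrame(
        [{"subject_id": sid, "score": s} for sid, s in sorted(scores.items())]
    ).to_csv(out_dir / "stress_scores.csv", index=False, float_format="%.6f")

    assessments = assess_hotspots(
        scores, labels, weight=config.fusion_weight, top_k=config.top_k
    )
    report = build_report(
        assessments,
        out_dir,
        lo=config.classify_cuts[0],
        hi=config.classify_cuts[1],
        plots=plots,
    )
    config.snapshot(out_dir)
    return SessionResult(features, hotspots, model, scores, assessments, report)
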