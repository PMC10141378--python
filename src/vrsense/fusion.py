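"""Fusion of behavioural stress with visual sentiment, and reporting.

Per hotspot, the behavioural stress score (from the HMM decode of the
whole session) is averaged with the hotspot's mean visual arousal score —
the visual scores over viewing directions are averaged first, then fused:

    fused = w * behavioural + (1 - w) * visual_mean,   w = 0.5 by default

Per subject, the five per-hotspot valence and fused-arousal values are
summarised by their mean and *population* standard deviation (denominator
n), and subjects are classified by banding the mean: valence below the low
cut is a negative experience, arousal below 0.5 a calm one.  Report values
are rounded to 3 decimals, half away from zero.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .reference import round_half_away
from .sentiment import ScreenshotLabel, group_labels, hotspot_visual_score

logger = logging.getLogger(__name__)

FUSION_WEIGHT = 0.5
#: Band cut points used in the published classification narrative.
CLASSIFY_CUTS = (0.3, 0.6)


def fuse_arousal(
    behavioural: float, visual_mean: float, weight: float = FUSION_WEIGHT
) -> float:
    """Weighted average of the behavioural stress and mean visual arousal.

    Both inputs and the weight must lie in [0, 1]; the result always lies
    between the two inputs (equal to ``visual_mean`` at weight 0 and to
    ``behavioural`` at weight 1).
    """
    for name, v in (
        ("behavioural", behavioural), ("visual_mean", visual_mean), ("weight", weight)
    ):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"fuse_arousal: {name}={v!r} outside [0, 1]")
    return weight * behavioural + (1.0 - weight) * visual_mean


def subject_summary(values: Sequence[float]) -> tuple[float, float]:
    """Mean and population SD of a per-hotspot vector, rounded to 3 decimals."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("subject_summary: empty vector")
    return (round_half_away(arr.mean(), 3), round_half_away(arr.std(ddof=0), 3))


def column_means(table) -> list[float]:
    """Per-hotspot mean over subjects, rounded to 3 decimals.

    ``table`` is a rectangular subjects-by-hotspots array; ragged input is
    rejected.
    """
    if isinstance(table, pd.DataFrame):
        arr = table.to_numpy(dtype=float)
    else:
        rows = [list(map(float, row)) for row in table]
        if rows and len({len(r) for r in rows}) != 1:
            raise ValidationError("column_means: ragged table")
        arr = np.asarray(rows, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValidationError("column_means: need a non-empty 2-D table")
    return [round_half_away(m, 3) for m in arr.mean(axis=0)]


def classify_subjects(
    means: Sequence[float],
    lo: float = CLASSIFY_CUTS[0],
    hi: float = CLASSIFY_CUTS[1],
    arousal_means: Sequence[float] | None = None,
) -> dict[str, int]:
    """Count subjects per band ``[0, lo) / [lo, hi) / [hi, 1]``.

    When ``arousal_means`` is given, additionally counts subjects whose
    mean arousal is below 0.5 (a calm overall experience).
    """
    arr = np.asarray(means, dtype=float)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ValidationError("classify_subjects: means must lie in [0, 1]")
    counts = {
        "low": int((arr < lo).sum()),
        "neutral": int(((arr >= lo) & (arr < hi)).sum()),
        "positive": int((arr >= hi).sum()),
    }
    if arousal_means is not None:
        counts["calm_arousal"] = int((np.asarray(arousal_means, float) < 0.5).sum())
    return counts


# ---------------------------------------------------------------------------
# Assessment assembly and report bundle


def assess_hotspots(
    stress_by_subject: Mapping[str, float],
    labels: Sequence[ScreenshotLabel],
    weight: float = FUSION_WEIGHT,
    top_k: int = 5,
) -> pd.DataFrame:
    """Per-subject, per-hotspot assessment rows.

    Combines each subject's behavioural stress score with the visual
    valence/arousal of each of their ``top_k`` hotspots.  A subject present
    in the stress results but missing labels for a rank is an error naming
    the hotspot.
    """
    grouped = group_labels(labels)
    rows = []
    for sid in sorted(stress_by_subject):
        if sid not in grouped:
            raise ValidationError(f"assess_hotspots: no screenshot labels for {sid!r}")
        for rank in range(1, top_k + 1):
            labs = grouped[sid].get(rank)
            if not labs:
                raise ValidationError(
                    f"assess_hotspots: no labels for hotspot rank {rank} of {sid!r}"
                )
            visual = hotspot_visual_score(labs)
            behavioural = float(stress_by_subject[sid])
            rows.append(
                {
                    "subject_id": sid,
                    "hotspot_rank": rank,
                    "valence": visual.valence,
                    "visual_arousal": visual.arousal,
                    "behavioural_stress": behavioural,
                    "fused_arousal": fuse_arousal(behavioural, visual.arousal, weight),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ReportBundle:
    """Paths of the files a report run produced."""

    assessments_csv: Path
    valence_table_csv: Path
    arousal_table_csv: Path
    summary_csv: Path
    classification_json: Path
    plot_paths: tuple[Path, ...] = ()


def _wide_table(assessments: pd.DataFrame, value: str, prefix: str) -> pd.DataFrame:
    """Subjects-by-hotspots table with Mean/SD columns and a column-mean row."""
    wide = assessments.pivot(index="subject_id", columns="hotspot_rank", values=value)
    if wide.isna().any().any():
        raise ValidationError(f"report: missing {value} for some subject/hotspot")
    # order subjects by their numeric suffix when present, else lexically
    def subject_key(s):
        tail = str(s).rsplit("_", 1)[-1]
        return (0, int(tail)) if tail.isdigit() else (1, str(s))
    wide = wide.loc[sorted(wide.index, key=subject_key)]
    wide.columns = [f"{prefix}_{int(r)}" for r in wide.columns]
    stats = wide.apply(lambda row: subject_summary(row.to_numpy()), axis=1)
    out = wide.round(6).copy()
    out["Mean"] = [m for m, _ in stats]
    out["SD"] = [s for _, s in stats]
    col_means = column_means(wide)
    out.loc["Mean Over Subjects"] = col_means + [np.nan, np.nan]
    return out


def build_report(
    assessments: pd.DataFrame,
    out_dir,
    lo: float = CLASSIFY_CUTS[0],
    hi: float = CLASSIFY_CUTS[1],
    plots: bool = False,
) -> ReportBundle:
    """Materialise the assessment tables, summaries and classification.

    Writes, under ``out_dir``: the raw assessments CSV; wide valence and
    fused-arousal tables (one row per subject plus a mean-over-subjects
    row, per-hotspot columns plus Mean/SD); a per-subject summary CSV; a
    classification JSON with band counts; and optionally one bar plot per
    subject.  Regenerating from identical inputs is byte-identical.
    """
    required = {
        "subject_id", "hotspot_rank", "valence", "visual_arousal",
        "behavioural_stress", "fused_arousal",
    }
    missing = required - set(assessments.columns)
    if missing:
        raise ValidationError(f"build_report: assessments missing columns {sorted(missing)}")
    if assessments.empty:
        raise ValidationError("build_report: no assessments to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    assessments = assessments.sort_values(["subject_id", "hotspot_rank"], kind="mergesort")
    assessments_csv = out_dir / "assessments.csv"
    assessments.to_csv(assessments_csv, index=False, float_format="%.6f")

    val = _wide_table(assessments, "valence", "V")
    aro = _wide_table(assessments, "fused_arousal", "A")
    valence_table_csv = out_dir / "valence_table.csv"
    arousal_table_csv = out_dir / "arousal_table.csv"
    val.to_csv(valence_table_csv, index_label="subject", float_format="%.3f")
    aro.to_csv(arousal_table_csv, index_label="subject", float_format="%.3f")

    subjects = [s for s in val.index if s != "Mean Over Subjects"]
    summary = pd.DataFrame(
        {
            "subject_id": subjects,
            "valence_mean": val.loc[subjects, "Mean"].to_numpy(),
            "valence_sd": val.loc[subjects, "SD"].to_numpy(),
            "arousal_mean": aro.loc[subjects, "Mean"].to_numpy(),
            "arousal_sd": aro.loc[subjects, "SD"].to_numpy(),
        }
    )
    summary_csv = out_dir / "summary.csv"
    summary.to_csv(summary_csv, index=False, float_format="%.3f")

    classification = {
        "valence_bands": classify_subjects(summary["valence_mean"], lo, hi),
        "arousal_bands": classify_subjects(summary["arousal_mean"], lo, hi),
        "calm_arousal_below_0.5": int((summary["arousal_mean"] < 0.5).sum()),
        "band_cuts": [lo, hi],
        "n_subjects": len(subjects),
    }
    classification_json = out_dir / "classification.json"
    classification_json.write_text(json.dumps(classification, indent=2, sort_keys=True))

    plot_paths: tuple[Path, ...] = ()
    if plots:
        plot_paths = tuple(_plot_subjects(assessments, out_dir))

    return ReportBundle(
        assessments_csv, valence_table_csv, arousal_table_csv,
        summary_csv, classification_json, plot_paths,
    )


def _plot_subjects(assessments: pd.DataFrame, out_dir: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    for sid, grp in assessments.groupby("subject_id", sort=True):
        fig, ax = plt.subplots(figsize=(5, 3))
        idx = np.arange(len(grp))
        ax.bar(idx - 0.2, grp["valence"], width=0.4, label="valence")
        ax.bar(idx + 0.2, grp["fused_arousal"], width=0.4, label="fused arousal")
        ax.set_xticks(idx, [f"H{r}" for r in grp["hotspot_rank"]])
        ax.set_ylim(0, 1)
        ax.set_ylabel("score")
        ax.set_title(str(sid))
        ax.legend(frameon=False)
        fig.tight_layout()
        path = out_dir / f"scores_{sid}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths.append(path)
    return paths
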