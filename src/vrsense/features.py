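"""Behavioural features from positional trajectories.

Four features summarise how a subject moves through the virtual space; fed
to the stress HMM they act as a behavioural proxy for arousal:

moving time (``mt``, s)
    Total time spent moving faster than a threshold (default 0.2 m/s,
    strict inequality).  Rushing tends to accompany nervousness, so more
    moving time reads as more stress.
track spread (``ts``, m)
    Maximum distance of any sample from the trajectory centroid — how much
    space the subject occupies.
wandering style (``ws``, cells/m)
    Number of distinct 0.1 m grid cells visited divided by total path
    length — circling in place versus purposeful straight lines.
hotspot spread (``hs``, m)
    Distance from the centre of the most-visited cell (by dwell time) to
    the trajectory centroid.

Features are extracted over non-overlapping (tumbling) 5-s windows aligned
at the first timestamp; a window needs at least two samples to produce a
feature vector, otherwise it is skipped with a logged notice.

Grid cells are axis-aligned squares; a position maps to the cell whose
index is ``round(x / cell_size)`` with ties rounded half away from zero, so
the cell ``(i, j)`` is centred at ``(i * cell_size, j * cell_size)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .errors import ValidationError
from .trajectory import Trajectory, speed_array

logger = logging.getLogger(__name__)

CELL_SIZE = 0.1  # m, side of a grid cell
SPEED_THRESHOLD = 0.2  # m/s, "rushing" cut-off
WINDOW_S = 5.0  # s, tumbling feature window

FEATURE_NAMES = ("mt", "ts", "ws", "hs")


@dataclass(frozen=True)
class CellIndex:
    """Integer index of one grid cell; centre at ``(i*cell_size, j*cell_size)``."""

    i: int
    j: int
    cell_size: float = CELL_SIZE

    @property
    def centre(self) -> tuple[float, float]:
        return (self.i * self.cell_size, self.j * self.cell_size)


@dataclass(frozen=True)
class FeatureVector:
    """The four behavioural features for one time window."""

    mt: float
    ts: float
    ws: float
    hs: float
    t_start: float
    t_end: float

    def as_array(self) -> np.ndarray:
        return np.array([self.mt, self.ts, self.ws, self.hs])


def _round_half_away(a: np.ndarray) -> np.ndarray:
    # numpy's round() is banker's rounding; grid assignment needs a
    # deterministic platform-independent tie rule.
    a = np.asarray(a, dtype=float)
    return np.sign(a) * np.floor(np.abs(a) + 0.5)


def assign_cell(x: float, y: float, cell_size: float = CELL_SIZE) -> CellIndex:
    """Map a position to its grid cell (ties round half away from zero)."""
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValidationError(f"assign_cell: non-finite position ({x!r}, {y!r})")
    i = int(_round_half_away(np.asarray(x) / cell_size))
    j = int(_round_half_away(np.asarray(y) / cell_size))
    return CellIndex(i, j, cell_size)


def cell_indices(traj: Trajectory, cell_size: float = CELL_SIZE) -> np.ndarray:
    """Per-sample cell indices as an ``(n, 2)`` int array."""
    i = _round_half_away(traj.x / cell_size).astype(int)
    j = _round_half_away(traj.y / cell_size).astype(int)
    return np.column_stack([i, j])


def trajectory_centre(traj: Trajectory) -> tuple[float, float]:
    """Arithmetic mean of the sample positions (the trajectory centroid)."""
    return (float(traj.x.mean()), float(traj.y.mean()))


def moving_time(
    traj: Trajectory,
    speed_threshold: float = SPEED_THRESHOLD,
    stat: Literal["sum", "mean"] = "sum",
) -> float:
    """Time spent with inter-sample speed strictly above the threshold.

    ``stat="sum"`` (default) totals the qualifying interval durations;
    ``stat="mean"`` averages them instead (an alternative reading of the
    same feature, exposed for comparison).  Fewer than two samples: 0.
    """
    v = speed_array(traj)
    if v.size == 0:
        return 0.0
    dt = np.diff(traj.t)
    moving = dt[v > speed_threshold]
    if stat == "sum":
        return float(moving.sum())
    if stat == "mean":
        return float(moving.mean()) if moving.size else 0.0
    raise ValidationError(f"moving_time: unknown stat {stat!r}")


def track_spread(traj: Trajectory) -> float:
    """Maximum Euclidean distance of any sample from the centroid."""
    cx, cy = trajectory_centre(traj)
    return float(np.hypot(traj.x - cx, traj.y - cy).max())


def path_length(traj: Trajectory) -> float:
    """Total Euclidean path length over consecutive samples."""
    if traj.n_samples < 2:
        return 0.0
    return float(np.hypot(np.diff(traj.x), np.diff(traj.y)).sum())


def wandering_style(traj: Trajectory, cell_size: float = CELL_SIZE) -> float:
    """Unique cells visited per metre of path; 0 for a zero-length path."""
    length = path_length(traj)
    if length == 0.0:
        return 0.0
    n_cells = np.unique(cell_indices(traj, cell_size), axis=0).shape[0]
    return float(n_cells) / length


def cell_dwell(
    traj: Trajectory, cell_size: float = CELL_SIZE
) -> tuple[dict[tuple[int, int], float], dict[tuple[int, int], int]]:
    """Dwell seconds and sample counts per visited cell.

    Each inter-sample interval's duration is attributed to the cell of its
    *starting* sample; the final sample contributes presence but no dwell.
    The dwell values therefore sum exactly to the trajectory duration.
    """
    idx = cell_indices(traj, cell_size)
    dwell: dict[tuple[int, int], float] = {}
    count: dict[tuple[int, int], int] = {}
    dt = np.diff(traj.t)
    for k in range(traj.n_samples):
        key = (int(idx[k, 0]), int(idx[k, 1]))
        count[key] = count.get(key, 0) + 1
        if k < dt.size:
            dwell[key] = dwell.get(key, 0.0) + float(dt[k])
        else:
            dwell.setdefault(key, 0.0)
    return dwell, count


def hotspot_cell(
    traj: Trajectory, cell_size: float = CELL_SIZE
) -> CellIndex:
    """The most-visited cell by dwell time.

    Ties break by higher sample count, then by lowest ``(i, j)``
    lexicographically, so the result is deterministic.
    """
    dwell, count = cell_dwell(traj, cell_size)
    key = min(dwell, key=lambda c: (-dwell[c], -count[c], c))
    return CellIndex(key[0], key[1], cell_size)


def hotspot_spread(
    traj: Trajectory,
    cell_size: float = CELL_SIZE,
    centre_mode: Literal["mode_cell", "mean_cell"] = "mode_cell",
) -> float:
    """Distance from the hotspot-cell centre to the trajectory centroid.

    ``centre_mode="mean_cell"`` instead uses the mean of all unique visited
    cell centres (an alternative reading, exposed for comparison).
    """
    cx, cy = trajectory_centre(traj)
    if centre_mode == "mode_cell":
        hx, hy = hotspot_cell(traj, cell_size).centre
    elif centre_mode == "mean_cell":
        cells = np.unique(cell_indices(traj, cell_size), axis=0)
        hx, hy = (cells[:, 0].mean() * cell_size, cells[:, 1].mean() * cell_size)
    else:
        raise ValidationError(f"hotspot_spread: unknown centre_mode {centre_mode!r}")
    return float(np.hypot(hx - cx, hy - cy))


def window_features(
    traj: Trajectory,
    window: float = WINDOW_S,
    speed_threshold: float = SPEED_THRESHOLD,
    cell_size: float = CELL_SIZE,
    moving_time_stat: Literal["sum", "mean"] = "sum",
    hotspot_centre: Literal["mode_cell", "mean_cell"] = "mode_cell",
) -> list[FeatureVector]:
    """Extract one :class:`FeatureVector` per complete tumbling window.

    Windows are ``[t_first + k*window, t_first + (k+1)*window)``; only
    complete windows are considered, and a window with fewer than two
    samples is skipped with a logged notice.
    """
    if window <= 0:
        raise ValidationError("window_features: window must be positive")
    n_windows = int(np.floor(traj.duration / window))
    if n_windows == 0:
        logger.info(
            "subject %s: trajectory of %.3f s shorter than one %g-s window; "
            "no features extracted",
            traj.subject_id, traj.duration, window,
        )
        return []
    out: list[FeatureVector] = []
    t0 = float(traj.t[0])
    for k in range(n_windows):
        lo, hi = t0 + k * window, t0 + (k + 1) * window
        sub = traj.slice_time(lo, hi)
        if sub is None or sub.n_samples < 2:
            logger.info(
                "subject %s: window [%.3f, %.3f) has <2 samples; skipped",
                traj.subject_id, lo, hi,
            )
            continue
        out.append(
            FeatureVector(
                mt=moving_time(sub, speed_threshold, moving_time_stat),
                ts=track_spread(sub),
                ws=wandering_style(sub, cell_size),
                hs=hotspot_spread(sub, cell_size, hotspot_centre),
                t_start=lo,
                t_end=hi,
            )
        )
    return out


def features_frame(
    features_by_subject: dict[str, Iterable[FeatureVector]]
) -> pd.DataFrame:
    """Flatten per-subject feature vectors into the features CSV layout."""
    rows = [
        {
            "subject_id": sid,
            "window_start_s": fv.t_start,
            "mt_s": fv.mt,
            "ts_m": fv.ts,
            "ws_cells_per_m": fv.ws,
            "hs_m": fv.hs,
        }
        for sid, fvs in features_by_subject.items()
        for fv in fvs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "window_start_s", "mt_s", "ts_m", "ws_cells_per_m", "hs_m",
        ],
    )


def frame_to_sequences(df: pd.DataFrame) -> dict[str, np.ndarray]:
    """Features CSV frame back to per-subject ``(T, 4)`` arrays, time-ordered."""
    out: dict[str, np.ndarray] = {}
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("window_start_s", kind="mergesort")
        out[str(sid)] = grp[["mt_s", "ts_m", "ws_cells_per_m", "hs_m"]].to_numpy(float)
    return out
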