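"""Trajectory data model and CSV I/O.

A trajectory is one subject's timestamped sequence of planar positions on
the virtual floor plane, in metres and seconds.  Positions are stored as
numpy arrays for the numeric pipeline; :class:`TrajectorySample` offers a
per-sample view.  Any vertical (``z``) component present in an input file
is ignored with a logged notice — all distances downstream are 2-D.

Sampling may be irregular: nothing here resamples or interpolates, and no
stage downstream assumes a uniform rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Default CSV column names (comma-separated, header row, UTF-8).
TRAJECTORY_COLUMNS = {"subject": "subject_id", "t": "t", "x": "x", "y": "y"}


@dataclass(frozen=True)
class TrajectorySample:
    """One timestamped position: time in seconds, x/y in metres."""

    t: float
    x: float
    y: float


@dataclass
class IntervalSpeed:
    """Average speed over one inter-sample interval.

    ``v`` is the Euclidean chord length between the two samples divided by
    the time gap, in m/s.
    """

    t_start: float
    t_end: float
    v: float


class Trajectory:
    """Ordered positional samples for one subject.

    Invariants (checked on construction): at least one sample, all values
    finite, timestamps strictly increasing.
    """

    __slots__ = ("subject_id", "t", "x", "y")

    def __init__(self, subject_id: str, t, x, y) -> None:
        self.subject_id = str(subject_id)
        self.t = np.asarray(t, dtype=float)
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self._validate()

    def _validate(self) -> None:
        if self.t.ndim != 1 or self.t.size == 0:
            raise ValidationError(
                f"trajectory {self.subject_id!r}: needs >=1 sample"
            )
        if not (self.t.size == self.x.size == self.y.size):
            raise ValidationError(
                f"trajectory {self.subject_id!r}: t/x/y length mismatch"
            )
        for name, arr in (("t", self.t), ("x", self.x), ("y", self.y)):
            if not np.all(np.isfinite(arr)):
                bad = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise ValidationError(
                    f"trajectory {self.subject_id!r}: non-finite {name} at row {bad}"
                )
        dt = np.diff(self.t)
        if dt.size and not np.all(dt > 0):
            bad = int(np.flatnonzero(dt <= 0)[0]) + 1
            raise ValidationError(
                f"trajectory {self.subject_id!r}: timestamps not strictly "
                f"increasing at sample index {bad} (t={self.t[bad]!r})"
            )

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        """Session length ``t_last - t_first`` in seconds (0 for one sample)."""
        return float(self.t[-1] - self.t[0])

    @property
    def samples(self) -> Iterator[TrajectorySample]:
        for ti, xi, yi in zip(self.t, self.x, self.y):
            yield TrajectorySample(float(ti), float(xi), float(yi))

    def slice_time(self, t_start: float, t_end: float) -> "Trajectory | None":
        """Sub-trajectory with samples in ``[t_start, t_end)``; None if empty."""
        lo = int(np.searchsorted(self.t, t_start, side="left"))
        hi = int(np.searchsorted(self.t, t_end, side="left"))
        if hi <= lo:
            return None
        return Trajectory(self.subject_id, self.t[lo:hi], self.x[lo:hi], self.y[lo:hi])


def speed_array(traj: Trajectory) -> np.ndarray:
    """Per-interval speeds as a float array of length ``n_samples - 1``."""
    if traj.n_samples < 2:
        return np.empty(0)
    d = np.hypot(np.diff(traj.x), np.diff(traj.y))
    return d / np.diff(traj.t)


def interval_speeds(traj: Trajectory) -> list[IntervalSpeed]:
    """Chord-distance / time-gap speed for each consecutive sample pair.

    Fewer than two samples yields an empty list (not an error).
    """
    v = speed_array(traj)
    return [
        IntervalSpeed(float(traj.t[i]), float(traj.t[i + 1]), float(v[i]))
        for i in range(v.size)
    ]


def read_trajectories(
    path, column_map: Mapping[str, str] | None = None
) -> dict[str, Trajectory]:
    """Read a trajectory CSV into one :class:`Trajectory` per subject.

    The file must contain the columns named by ``column_map`` (defaults:
    ``subject_id, t, x, y``).  An optional ``z`` column is accepted and
    ignored with a logged notice.  Samples are sorted by time within each
    subject; a repeated ``(subject, t)`` pair is rejected.

    Raises
    ------
    FormatError
        if a required column is missing.
    ValidationError
        on duplicate timestamps or non-finite values (with the row index).
    """
    cols = dict(TRAJECTORY_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, float_precision="round_trip")
    for key in ("subject", "t", "x", "y"):
        if cols[key] not in df.columns:
            raise FormatError(
                f"{path}: missing required column {cols[key]!r}"
            )
    if "z" in df.columns:
        logger.info("%s: ignoring vertical 'z' column (planar analysis)", path)

    out: dict[str, Trajectory] = {}
    for subject, grp in df.groupby(cols["subject"], sort=True):
        grp = grp.sort_values(cols["t"], kind="mergesort")
        t = grp[cols["t"]].to_numpy(dtype=float)
        dup = np.flatnonzero(np.diff(t) == 0)
        if dup.size:
            row = int(grp.index[dup[0] + 1])
            raise ValidationError(
                f"{path}: duplicate timestamp t={t[dup[0]]!r} for subject "
                f"{subject!r} (input row {row})"
            )
        out[str(subject)] = Trajectory(
            str(subject),
            t,
            grp[cols["x"]].to_numpy(dtype=float),
            grp[cols["y"]].to_numpy(dtype=float),
        )
    return out


def write_trajectories(trajectories: Mapping[str, Trajectory], path) -> None:
    """Write trajectories back to CSV in the canonical column order."""
    frames = [
        pd.DataFrame(
            {"subject_id": tr.subject_id, "t": tr.t, "x": tr.x, "y": tr.y}
        )
        for tr in trajectories.values()
    ]
    # %.17g keeps float64 values bit-exact across a write/read cycle
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")
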