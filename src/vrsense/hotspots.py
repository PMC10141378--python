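"""Session-level hotspot identification.

A *hotspot* is a grid cell where a subject accumulated the most dwell time
over the whole session.  The top-ranked hotspots are the evaluation sites:
screenshots of the virtual space are taken from each hotspot in several
viewing directions (4 by default) and scored for visual sentiment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .features import CELL_SIZE, CellIndex, cell_dwell
from .trajectory import Trajectory

TOP_K = 5
N_DIRECTIONS = 4


@dataclass(frozen=True)
class HotspotRecord:
    """One ranked hotspot: cell, accumulated dwell seconds, 1-based rank."""

    cell: CellIndex
    dwell: float
    rank: int
    n_directions: int = N_DIRECTIONS


def visit_table(
    traj: Trajectory, cell_size: float = CELL_SIZE
) -> dict[CellIndex, float]:
    """Dwell seconds per visited cell over the whole session.

    Interval durations are attributed to the starting sample's cell, so the
    dwell values sum to the trajectory duration.  Fewer than two samples
    yields an empty mapping.
    """
    if traj.n_samples < 2:
        return {}
    dwell, _ = cell_dwell(traj, cell_size)
    return {CellIndex(i, j, cell_size): s for (i, j), s in dwell.items()}


def top_hotspots(
    table: Mapping[CellIndex, float],
    k: int = TOP_K,
    n_directions: int = N_DIRECTIONS,
) -> list[HotspotRecord]:
    """The ``k`` most-dwelt cells, ranked by descending dwell.

    Ties break by lowest ``(i, j)`` lexicographically; fewer than ``k``
    cells returns them all.
    """
    if k < 1:
        raise ValueError("top_hotspots: k must be >= 1")
    ordered = sorted(table.items(), key=lambda kv: (-kv[1], (kv[0].i, kv[0].j)))
    return [
        HotspotRecord(cell, float(dwell), rank, n_directions)
        for rank, (cell, dwell) in enumerate(ordered[:k], start=1)
    ]


def hotspots_frame(records_by_subject: Mapping[str, list[HotspotRecord]]) -> pd.DataFrame:
    """Flatten per-subject hotspot records into the hotspots CSV layout."""
    rows = [
        {
            "subject_id": sid,
            "rank": rec.rank,
            "cell_i": rec.cell.i,
            "cell_j": rec.cell.j,
            "dwell_s": rec.dwell,
        }
        for sid, recs in records_by_subject.items()
        for rec in recs
    ]
    return pd.DataFrame(rows, columns=["subject_id", "rank", "cell_i", "cell_j", "dwell_s"])
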