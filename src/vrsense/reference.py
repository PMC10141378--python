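"""Reference per-hotspot scores from a published 10-subject VR evaluation.

Ten subjects explored a social VR village; for each subject the five
most-visited hotspots were scored for visual valence and for fused arousal
(behavioural stress averaged with visual arousal).  The published tables
print every per-hotspot entry to 3 decimals together with each subject's
mean, population SD, and a per-hotspot mean over subjects.  They serve
here as a regression fixture: the summary statistics must be recomputable
from the per-hotspot entries.

Printed entries are themselves roundings.  Any value whose 3-decimal form
is the half-away-from-zero rounding of a distinct multiple of 0.0125 (the
granularity of averaging a quarter-resolution behavioural score with four
class scores from {0, 0.5, 1}) — e.g. 0.163, 0.288, 0.438, 0.688, 0.813 —
is restored to that underlying four-decimal value by :func:`dequantize`
before statistics are recomputed.  With this restoration every printed
mean and SD cell reproduces exactly at 3 decimals; from the raw printed
entries two SD cells would differ by one unit in the last digit.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

SUBJECTS = [f"Subject_{i}" for i in range(1, 11)]
HOTSPOT_COLS = [f"H_{r}" for r in range(1, 6)]

# Printed table: per-hotspot valence, then subject mean and population SD.
VALENCE_PRINTED = {
    "Subject_1": ([0.500, 0.375, 0.750, 0.750, 0.500], 0.575, 0.150),
    "Subject_2": ([0.625, 0.000, 0.000, 0.000, 0.125], 0.150, 0.242),
    "Subject_3": ([0.750, 0.500, 0.375, 0.875, 1.000], 0.700, 0.232),
    "Subject_4": ([0.875, 0.500, 0.875, 0.625, 0.375], 0.650, 0.200),
    "Subject_5": ([0.000, 0.625, 0.500, 0.875, 0.000], 0.400, 0.348),
    "Subject_6": ([0.125, 0.125, 0.125, 0.500, 0.000], 0.175, 0.170),
    "Subject_7": ([0.125, 0.000, 0.625, 0.500, 0.375], 0.325, 0.232),
    "Subject_8": ([0.500, 0.375, 0.625, 0.500, 0.500], 0.500, 0.079),
    "Subject_9": ([0.250, 0.750, 0.625, 0.125, 0.750], 0.500, 0.262),
    "Subject_10": ([0.500, 0.125, 0.500, 0.000, 0.625], 0.350, 0.242),
}
VALENCE_COLUMN_MEANS_PRINTED = [0.425, 0.338, 0.500, 0.475, 0.425]

# Printed table: per-hotspot fused arousal, subject mean, population SD.
AROUSAL_PRINTED = {
    "Subject_1": ([0.163, 0.225, 0.100, 0.163, 0.000], 0.130, 0.076),
    "Subject_2": ([0.523, 0.291, 0.293, 0.294, 0.641], 0.408, 0.147),
    "Subject_3": ([0.350, 0.225, 0.350, 0.350, 0.350], 0.325, 0.050),
    "Subject_4": ([0.225, 0.225, 0.162, 0.225, 0.163], 0.200, 0.031),
    "Subject_5": ([0.825, 0.350, 0.438, 0.350, 0.350], 0.463, 0.184),
    "Subject_6": ([0.625, 0.625, 0.288, 0.100, 0.288], 0.385, 0.208),
    "Subject_7": ([0.475, 0.813, 0.163, 0.100, 0.225], 0.355, 0.262),
    "Subject_8": ([0.688, 0.288, 0.225, 0.225, 0.225], 0.330, 0.180),
    "Subject_9": ([0.561, 0.100, 0.000, 0.425, 0.163], 0.250, 0.210),
    "Subject_10": ([0.288, 0.100, 0.163, 0.288, 0.225], 0.213, 0.073),
}
AROUSAL_COLUMN_MEANS_PRINTED = [0.472, 0.324, 0.218, 0.252, 0.263]


def round_half_away(x: float, ndigits: int = 3) -> float:
    """Round half away from zero at ``ndigits`` decimals (report convention).

    Operates on the shortest decimal representation of ``x``, so 0.1625
    rounds to 0.163 regardless of its binary representation.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


def dequantize(v: float, step: float = 0.0125) -> float:
    """Restore a printed 3-decimal value to its underlying ``step`` multiple.

    Applies only when the printed value is exactly the 3-decimal
    half-away-from-zero rounding of the nearest ``step`` multiple and
    differs from it (e.g. 0.163 -> 0.1625); otherwise returns ``v``.
    """
    m = round(v / step) * step
    if m != v and round_half_away(m, 3) == v:
        return m
    return v


def _frame(printed: dict) -> pd.DataFrame:
    data = [[dequantize(v) for v in printed[s][0]] for s in SUBJECTS]
    return pd.DataFrame(data, index=SUBJECTS, columns=HOTSPOT_COLS)


def valence_scores() -> pd.DataFrame:
    """Per-hotspot valence entries (dequantized), subjects x hotspots."""
    return _frame(VALENCE_PRINTED)


def arousal_scores() -> pd.DataFrame:
    """Per-hotspot fused-arousal entries (dequantized), subjects x hotspots."""
    return _frame(AROUSAL_PRINTED)


def printed_summaries(which: str) -> pd.DataFrame:
    """Printed per-subject Mean/SD cells for ``"valence"`` or ``"arousal"``."""
    printed = VALENCE_PRINTED if which == "valence" else AROUSAL_PRINTED
    return pd.DataFrame(
        {
            "mean": [printed[s][1] for s in SUBJECTS],
            "sd": [printed[s][2] for s in SUBJECTS],
        },
        index=SUBJECTS,
    )


def printed_column_means(which: str) -> np.ndarray:
    return np.array(
        VALENCE_COLUMN_MEANS_PRINTED if which == "valence"
        else AROUSAL_COLUMN_MEANS_PRINTED
    )
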