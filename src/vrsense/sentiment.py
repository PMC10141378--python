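"""Three-level visual valence/arousal scoring of hotspot screenshots.

The dimensional model of emotion places an experience on two axes:
*valence* (negative … positive, pleasantness) and *arousal* (calm …
excited, activation).  Each screenshot taken at a hotspot is classified
into one of three levels per axis; classes map onto the [0, 1] fusion
scale as 0, 0.5 and 1, and a score maps back to a class through the bands
``[0, lo) / [lo, hi) / [hi, 1]`` (default cuts 0.33 and 0.66).

Scoring itself is a pluggable provider: the reference path is the
table-driven scorer that reads class labels from a CSV (one row per
subject, hotspot rank and viewing direction); a toy image-statistics
scorer (brightness/saturation bands) is included for end-to-end smoke
tests only and makes no claim of perceptual validity.  Averaging the
per-direction class scores of a hotspot gives its visual sentiment score —
with 4 directions, always a multiple of 0.125.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Literal, Protocol, Sequence

import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

THRESHOLDS = (0.33, 0.66)


class Valence(str, Enum):
    NEGATIVE = "negative"
    NEUTRAL = "neutral"
    POSITIVE = "positive"


class Arousal(str, Enum):
    CALM = "calm"
    NEUTRAL = "neutral"
    EXCITED = "excited"


_CLASS_VALUE = {
    Valence.NEGATIVE: 0.0, Valence.NEUTRAL: 0.5, Valence.POSITIVE: 1.0,
    Arousal.CALM: 0.0, Arousal.NEUTRAL: 0.5, Arousal.EXCITED: 1.0,
}


@dataclass(frozen=True)
class SentimentClass:
    """One screenshot's class pair on the two emotion axes."""

    valence: Valence
    arousal: Arousal


@dataclass(frozen=True)
class SentimentScore:
    """Valence and arousal scores, each in [0, 1]."""

    valence: float
    arousal: float

    def __post_init__(self) -> None:
        for name, v in (("valence", self.valence), ("arousal", self.arousal)):
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"SentimentScore: {name}={v!r} outside [0, 1]")


@dataclass(frozen=True)
class ScreenshotLabel:
    """Classified screenshot: who, which hotspot, which viewing direction."""

    subject_id: str
    hotspot_rank: int
    direction: int
    sentiment: SentimentClass


def parse_valence(label: str) -> Valence:
    try:
        return Valence(str(label).strip().lower())
    except ValueError:
        raise FormatError(
            f"unknown valence class {label!r} (expected negative/neutral/positive)"
        ) from None


def parse_arousal(label: str) -> Arousal:
    try:
        return Arousal(str(label).strip().lower())
    except ValueError:
        raise FormatError(
            f"unknown arousal class {label!r} (expected calm/neutral/excited)"
        ) from None


def class_to_score(c: SentimentClass) -> SentimentScore:
    """Map a class pair to scores: negative/calm 0, neutral 0.5, positive/excited 1."""
    return SentimentScore(_CLASS_VALUE[c.valence], _CLASS_VALUE[c.arousal])


def score_to_class(
    s: float,
    dimension: Literal["valence", "arousal"] = "valence",
    thresholds: tuple[float, float] = THRESHOLDS,
) -> Valence | Arousal:
    """Band a [0, 1] score back into a 3-level class.

    ``[0, lo)`` is negative/calm, ``[lo, hi)`` neutral, ``[hi, 1]``
    positive/excited (the top band includes its lower bound).
    """
    lo, hi = thresholds
    if not 0.0 <= s <= 1.0:
        raise ValidationError(f"score_to_class: score {s!r} outside [0, 1]")
    if not 0.0 < lo < hi <= 1.0:
        raise ValidationError(f"score_to_class: bad thresholds {thresholds!r}")
    ladder = (Valence.NEGATIVE, Valence.NEUTRAL, Valence.POSITIVE) \
        if dimension == "valence" else (Arousal.CALM, Arousal.NEUTRAL, Arousal.EXCITED)
    if s < lo:
        return ladder[0]
    if s < hi:
        return ladder[1]
    return ladder[2]


def hotspot_visual_score(labels: Sequence[ScreenshotLabel]) -> SentimentScore:
    """Average the per-direction class scores of one hotspot's screenshots."""
    if not labels:
        raise ValidationError("hotspot_visual_score: no labels for this hotspot")
    scores = [class_to_score(lab.sentiment) for lab in labels]
    n = len(scores)
    return SentimentScore(
        sum(s.valence for s in scores) / n,
        sum(s.arousal for s in scores) / n,
    )


# ---------------------------------------------------------------------------
# Label CSV I/O (the reference scoring path)

LABEL_COLUMNS = ["subject_id", "hotspot_rank", "direction", "valence_class", "arousal_class"]


def read_labels(path) -> list[ScreenshotLabel]:
    """Read a screenshot-labels CSV (one row per subject/rank/direction)."""
    df = pd.read_csv(path)
    for col in LABEL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ScreenshotLabel(
                subject_id=str(row.subject_id),
                hotspot_rank=int(row.hotspot_rank),
                direction=int(row.direction),
                sentiment=SentimentClass(
                    parse_valence(row.valence_class), parse_arousal(row.arousal_class)
                ),
            )
        )
    return out


def write_labels(labels: Iterable[ScreenshotLabel], path) -> None:
    pd.DataFrame(
        [
            {
                "subject_id": lab.subject_id,
                "hotspot_rank": lab.hotspot_rank,
                "direction": lab.direction,
                "valence_class": lab.sentiment.valence.value,
                "arousal_class": lab.sentiment.arousal.value,
            }
            for lab in labels
        ],
        columns=LABEL_COLUMNS,
    ).to_csv(path, index=False)


def group_labels(
    labels: Iterable[ScreenshotLabel],
) -> dict[str, dict[int, list[ScreenshotLabel]]]:
    """Labels nested by subject then hotspot rank, directions sorted."""
    out: dict[str, dict[int, list[ScreenshotLabel]]] = {}
    for lab in labels:
        out.setdefault(lab.subject_id, {}).setdefault(lab.hotspot_rank, []).append(lab)
    for ranks in out.values():
        for labs in ranks.values():
            labs.sort(key=lambda l: l.direction)
    return out


# ---------------------------------------------------------------------------
# Pluggable screenshot scorers

#: Screenshot files are named ``<subject>_h<rank>_d<direction>.<ext>``.
FILENAME_PATTERN = re.compile(r"^(?P<subject>.+)_h(?P<rank>\d+)_d(?P<direction>\d+)$")


class ScreenshotScorer(Protocol):
    """Anything that turns an image file into a :class:`SentimentClass`."""

    def score(self, path: Path) -> SentimentClass: ...


class TableScorer:
    """Reference provider: looks classes up in a labels CSV by
    (subject, rank, direction) parsed from the screenshot filename."""

    def __init__(self, labels_csv) -> None:
        self._table = {
            (lab.subject_id, lab.hotspot_rank, lab.direction): lab.sentiment
            for lab in read_labels(labels_csv)
        }

    def score(self, path: Path) -> SentimentClass:
        key = _parse_filename(path)
        try:
            return self._table[key]
        except KeyError:
            raise FormatError(
                f"{path}: no label for subject={key[0]!r} rank={key[1]} "
                f"direction={key[2]}"
            ) from None


class BrightnessSaturationScorer:
    """Toy image-statistics scorer for smoke tests only.

    Valence follows mean brightness and arousal mean saturation, banded in
    thirds of the 0–255 range.  Deterministic, but not a perceptual model.
    """

    def score(self, path: Path) -> SentimentClass:
        from PIL import Image

        with Image.open(path) as im:
            hsv = im.convert("HSV")
            stats = hsv.getdata()
            n = len(stats)
            sat = sum(p[1] for p in stats) / n
            val = sum(p[2] for p in stats) / n
        def band(x, ladder):
            return ladder[0] if x < 85 else ladder[1] if x < 170 else ladder[2]
        return SentimentClass(
            band(val, (Valence.NEGATIVE, Valence.NEUTRAL, Valence.POSITIVE)),
            band(sat, (Arousal.CALM, Arousal.NEUTRAL, Arousal.EXCITED)),
        )


def _parse_filename(path) -> tuple[str, int, int]:
    stem = Path(path).stem
    m = FILENAME_PATTERN.match(stem)
    if not m:
        raise FormatError(
            f"{path}: filename does not match '<subject>_h<rank>_d<direction>'"
        )
    return (m.group("subject"), int(m.group("rank")), int(m.group("direction")))


def score_screenshots(
    provider: ScreenshotScorer, images: Iterable
) -> list[ScreenshotLabel]:
    """Score a batch of screenshot files, one label per readable image.

    An unreadable or unlabellable file is skipped with a logged warning and
    the batch continues.
    """
    out: list[ScreenshotLabel] = []
    for img in images:
        path = Path(img)
        try:
            subject, rank, direction = _parse_filename(path)
            sentiment = provider.score(path)
        except (FormatError, OSError) as exc:
            logger.warning("score_screenshots: skipping %s (%s)", path, exc)
            continue
        out.append(ScreenshotLabel(subject, rank, direction, sentiment))
    return out
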