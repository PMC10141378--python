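import itertools

import numpy as np
import pandas as pd
import pytest
from PIL import Image

from vrsense.errors import FormatError, ValidationError
from vrsense.sentiment import (
    Arousal,
    BrightnessSaturationScorer,
    ScreenshotLabel,
    SentimentClass,
    SentimentScore,
    TableScorer,
    Valence,
    class_to_score,
    hotspot_visual_score,
    read_labels,
    score_screenshots,
    score_to_class,
    write_labels,
)

ALL_VALENCE = list(Valence)
ALL_AROUSAL = list(Arousal)


def label(v, a, subject="s", rank=1, direction=0):
    return ScreenshotLabel(subject, rank, direction, SentimentClass(v, a))


class TestClassScoreMapping:
    @pytest.mark.parametrize(
        "v, a, expected",
        [
            (Valence.NEGATIVE, Arousal.CALM, (0.0, 0.0)),
            (Valence.NEUTRAL, Arousal.NEUTRAL, (0.5, 0.5)),
            (Valence.POSITIVE, Arousal.EXCITED, (1.0, 1.0)),
        ],
    )
    def test_class_to_score(self, v, a, expected):
        s = class_to_score(SentimentClass(v, a))
        assert (s.valence, s.arousal) == expected

    @pytest.mark.parametrize(
        "score, expected",
        [
            (0.32, Valence.NEGATIVE),  # just under the low cut
            (0.33, Valence.NEUTRAL),  # low cut belongs to the middle band
            (0.66, Valence.POSITIVE),  # top band includes its lower bound
            (0.0, Valence.NEGATIVE),
            (1.0, Valence.POSITIVE),
        ],
    )
    def test_score_to_class_bands(self, score, expected):
        assert score_to_class(score, "valence") is expected

    def test_arousal_ladder(self):
        assert score_to_class(0.1, "arousal") is Arousal.CALM
        assert score_to_class(0.9, "arousal") is Arousal.EXCITED

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            score_to_class(1.2)
        with pytest.raises(ValidationError):
            score_to_class(-0.01)

    @pytest.mark.parametrize("v", ALL_VALENCE)
    @pytest.mark.parametrize("a", ALL_AROUSAL)
    def test_round_trip_all_classes(self, v, a):
        s = class_to_score(SentimentClass(v, a))
        assert score_to_class(s.valence, "valence") is v
        assert score_to_class(s.arousal, "arousal") is a

    def test_score_bounds_enforced(self):
        with pytest.raises(ValidationError):
            SentimentScore(1.4, 0.0)


class TestHotspotVisualScore:
    def test_all_neutral(self):
        labs = [label(Valence.NEUTRAL, Arousal.NEUTRAL, direction=d) for d in range(4)]
        s = hotspot_visual_score(labs)
        assert (s.valence, s.arousal) == (0.5, 0.5)

    def test_mixed_average(self):
        vs = [Valence.POSITIVE, Valence.POSITIVE, Valence.NEUTRAL, Valence.NEGATIVE]
        labs = [label(v, Arousal.CALM, direction=d) for d, v in enumerate(vs)]
        assert hotspot_visual_score(labs).valence == pytest.approx(0.625)

    def test_four_direction_scores_are_eighths(self):
        # every 4-combination averages to a multiple of 1/8
        for combo in itertools.product(ALL_VALENCE, repeat=4):
            labs = [label(v, Arousal.CALM, direction=d) for d, v in enumerate(combo)]
            s = hotspot_visual_score(labs)
            assert (s.valence * 8) == pytest.approx(round(s.valence * 8))
            lo = min(class_to_score(l.sentiment).valence for l in labs)
            hi = max(class_to_score(l.sentiment).valence for l in labs)
            assert lo <= s.valence <= hi  # convex hull of inputs

    def test_permutation_invariant(self, rng):
        vs = [Valence.POSITIVE, Valence.NEGATIVE, Valence.NEUTRAL, Valence.POSITIVE]
        labs = [label(v, Arousal.CALM, direction=d) for d, v in enumerate(vs)]
        shuffled = list(labs)
        rng.shuffle(shuffled)
        assert hotspot_visual_score(labs) == hotspot_visual_score(shuffled)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError, match="no labels"):
            hotspot_visual_score([])


class TestLabelsIO:
    def test_round_trip(self, tmp_path):
        labs = [
            label(Valence.POSITIVE, Arousal.CALM, "Subject_1", 1, d) for d in range(4)
        ]
        path = tmp_path / "labels.csv"
        write_labels(labs, path)
        assert read_labels(path) == labs

    def test_missing_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"subject_id": ["a"]}).to_csv(path, index=False)
        with pytest.raises(FormatError, match="hotspot_rank"):
            read_labels(path)

    def test_unknown_class(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame(
            {"subject_id": ["a"], "hotspot_rank": [1], "direction": [0],
             "valence_class": ["great"], "arousal_class": ["calm"]}
        ).to_csv(path, index=False)
        with pytest.raises(FormatError, match="great"):
            read_labels(path)


class TestScorers:
    def make_images(self, tmp_path):
        dark = tmp_path / "s1_h1_d0.png"
        Image.new("RGB", (8, 8), (5, 5, 5)).save(dark)
        bright = tmp_path / "s1_h1_d1.png"
        Image.new("RGB", (8, 8), (250, 40, 40)).save(bright)  # bright, saturated
        return dark, bright

    def test_table_scorer_passthrough(self, tmp_path):
        labs = [
            label(v, a, "s1", 1, d)
            for d, (v, a) in enumerate(
                [(Valence.POSITIVE, Arousal.CALM), (Valence.NEGATIVE, Arousal.EXCITED),
                 (Valence.NEUTRAL, Arousal.NEUTRAL), (Valence.POSITIVE, Arousal.CALM)]
            )
        ]
        csv = tmp_path / "labels.csv"
        write_labels(labs, csv)
        for d in range(4):
            Image.new("RGB", (4, 4)).save(tmp_path / f"s1_h1_d{d}.png")
        scorer = TableScorer(csv)
        out = score_screenshots(
            scorer, [tmp_path / f"s1_h1_d{d}.png" for d in range(4)]
        )
        assert out == labs

    def test_heuristic_scorer_separates_dark_and_bright(self, tmp_path):
        dark, bright = self.make_images(tmp_path)
        scorer = BrightnessSaturationScorer()
        a, b = scorer.score(dark), scorer.score(bright)
        assert a != b
        assert a.valence is Valence.NEGATIVE
        assert b.valence is Valence.POSITIVE
        assert scorer.score(dark) == a  # deterministic

    def test_missing_file_skipped(self, tmp_path):
        dark, bright = self.make_images(tmp_path)
        out = score_screenshots(
            BrightnessSaturationScorer(), [dark, tmp_path / "s1_h1_d9.png", bright]
        )
        assert len(out) == 2

    def test_unparsable_filename_skipped(self, tmp_path):
        weird = tmp_path / "screenshot.png"
        Image.new("RGB", (4, 4)).save(weird)
        assert score_screenshots(BrightnessSaturationScorer(), [weird]) == []
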