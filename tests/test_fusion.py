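import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vrsense import reference
from vrsense.errors import ValidationError
from vrsense.fusion import (
    assess_hotspots,
    build_report,
    classify_subjects,
    column_means,
    fuse_arousal,
    subject_summary,
)
from vrsense.sentiment import Arousal, ScreenshotLabel, SentimentClass, Valence

unit = st.floats(0.0, 1.0)


class TestFuseArousal:
    def test_equal_inputs_idempotent(self):
        for x in (0.0, 0.3, 1.0):
            assert fuse_arousal(x, x) == pytest.approx(x)

    def test_midpoint(self):
        assert fuse_arousal(0.0, 1.0) == pytest.approx(0.5)

    def test_reference_granularity_case(self):
        assert fuse_arousal(0.2, 0.125) == pytest.approx(0.1625)

    def test_weight_endpoints(self):
        assert fuse_arousal(0.7, 0.2, weight=1.0) == pytest.approx(0.7)
        assert fuse_arousal(0.7, 0.2, weight=0.0) == pytest.approx(0.2)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(unit, unit, unit)
    def test_bounded_between_inputs(self, b, v, w):
        f = fuse_arousal(b, v, w)
        assert min(b, v) - 1e-12 <= f <= max(b, v) + 1e-12

    def test_range_errors(self):
        with pytest.raises(ValidationError):
            fuse_arousal(1.2, 0.5)
        with pytest.raises(ValidationError):
            fuse_arousal(0.5, -0.1)


class TestSubjectSummary:
    def test_reference_subject_rows(self):
        # printed Mean/SD cells reproduce with the population convention
        mean, sd = subject_summary([0.500, 0.375, 0.750, 0.750, 0.500])
        assert (mean, sd) == (0.575, 0.150)
        mean, sd = subject_summary([0.500, 0.375, 0.625, 0.500, 0.500])
        assert (mean, sd) == (0.500, 0.079)

    def test_constant_vector_sd_zero(self):
        assert subject_summary([0.4, 0.4, 0.4]) == (0.4, 0.0)

    def test_sample_sd_would_differ(self):
        # the same row under the n-1 convention gives 0.168, not 0.150
        row = np.array([0.500, 0.375, 0.750, 0.750, 0.500])
        assert round(row.std(ddof=1), 3) == 0.168

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            subject_summary([])


class TestColumnMeans:
    def test_reference_columns(self):
        assert column_means(reference.valence_scores())[2] == 0.500
        assert column_means(reference.arousal_scores())[0] == 0.472

    def test_single_row_identity(self):
        assert column_means([[0.1, 0.2, 0.3]]) == [0.1, 0.2, 0.3]

    def test_ragged_rejected(self):
        with pytest.raises(ValidationError, match="ragged"):
            column_means([[0.1, 0.2], [0.3]])


class TestClassifySubjects:
    def test_reference_valence_bands(self):
        means = reference.valence_scores().mean(axis=1)
        counts = classify_subjects(means, lo=0.3, hi=0.6)
        assert counts["low"] == 2

    def test_reference_arousal_all_calm(self):
        means = reference.arousal_scores().mean(axis=1)
        counts = classify_subjects([0.5] * 10, arousal_means=means)
        assert counts["calm_arousal"] == 10

    def test_all_zero(self):
        counts = classify_subjects([0.0] * 7)
        assert (counts["low"], counts["neutral"], counts["positive"]) == (7, 0, 0)

    def test_order_invariant(self, rng):
        means = rng.uniform(0, 1, 10)
        a = classify_subjects(means)
        b = classify_subjects(means[::-1])
        assert a == b

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            classify_subjects([1.5])


def synthetic_assessments(n_subjects=10, top_k=5, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(1, n_subjects + 1):
        stress = float(rng.uniform(0, 1))
        for r in range(1, top_k + 1):
            visual = float(rng.integers(0, 9)) / 8
            rows.append(
                {
                    "subject_id": f"Subject_{s}",
                    "hotspot_rank": r,
                    "valence": float(rng.integers(0, 9)) / 8,
                    "visual_arousal": visual,
                    "behavioural_stress": stress,
                    "fused_arousal": 0.5 * stress + 0.5 * visual,
                }
            )
    return pd.DataFrame(rows)


class TestBuildReport:
    def test_shapes_and_classification(self, tmp_path):
        bundle = build_report(synthetic_assessments(), tmp_path)
        val = pd.read_csv(bundle.valence_table_csv)
        assert len(val) == 11  # 10 subjects + mean-over-subjects row
        assert list(val.columns) == ["subject", "V_1", "V_2", "V_3", "V_4", "V_5",
                                     "Mean", "SD"]
        cls = json.loads(bundle.classification_json.read_text())
        assert cls["n_subjects"] == 10
        assert sum(cls["valence_bands"].values()) == 10

    def test_regeneration_byte_identical(self, tmp_path):
        a_dir, b_dir = tmp_path / "a", tmp_path / "b"
        ass = synthetic_assessments(seed=3)
        b1 = build_report(ass, a_dir)
        b2 = build_report(ass.sample(frac=1, random_state=1), b_dir)  # shuffled rows
        for f1, f2 in [
            (b1.valence_table_csv, b2.valence_table_csv),
            (b1.arousal_table_csv, b2.arousal_table_csv),
            (b1.summary_csv, b2.summary_csv),
            (b1.classification_json, b2.classification_json),
        ]:
            assert f1.read_bytes() == f2.read_bytes()

    def test_single_subject(self, tmp_path):
        bundle = build_report(synthetic_assessments(n_subjects=1), tmp_path)
        summary = pd.read_csv(bundle.summary_csv)
        assert len(summary) == 1

    def test_missing_column_rejected(self, tmp_path):
        with pytest.raises(ValidationError, match="missing columns"):
            build_report(pd.DataFrame({"subject_id": ["a"]}), tmp_path)

    def test_plots_written(self, tmp_path):
        bundle = build_report(
            synthetic_assessments(n_subjects=2), tmp_path, plots=True
        )
        assert len(bundle.plot_paths) == 2
        assert all(p.exists() for p in bundle.plot_paths)


class TestAssessHotspots:
    def labels(self, subjects=("s1",), ranks=(1, 2)):
        out = []
        for s in subjects:
            for r in ranks:
                for d in range(4):
                    out.append(
                        ScreenshotLabel(
                            s, r, d, SentimentClass(Valence.NEUTRAL, Arousal.CALM)
                        )
                    )
        return out

    def test_rows_and_fusion(self):
        df = assess_hotspots({"s1": 0.4}, self.labels(), top_k=2)
        assert len(df) == 2
        assert df["visual_arousal"].tolist() == [0.0, 0.0]
        assert df["fused_arousal"].tolist() == pytest.approx([0.2, 0.2])

    def test_missing_rank_named(self):
        with pytest.raises(ValidationError, match="rank 2"):
            assess_hotspots({"s1": 0.4}, self.labels(ranks=(1,)), top_k=2)

    def test_missing_subject_named(self):
        with pytest.raises(ValidationError, match="s2"):
            assess_hotspots({"s2": 0.4}, self.labels(), top_k=2)
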