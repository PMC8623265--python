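"""Study-design taxonomy, pairings protocol and correlation analysis."""

import numpy as np
import pandas as pd
import pytest

import semgbench as sb
from semgbench.core import ConditionKey, all_condition_keys
from semgbench.evaluation import (
    ExperimentResult,
    RESULT_COLUMNS,
    _evaluate_split,
    enumerate_combined_models,
    pearson_trend,
    run_combined,
    run_pairing,
)
from semgbench.features import FEATURE_COLUMNS


class TestConditionKeys:
    def test_exactly_18_distinct_keys(self):
        keys = all_condition_keys()
        assert len(keys) == len(set(keys)) == 18

    def test_label_round_trip(self):
        key = ConditionKey("A", "b", 30)
        assert key.label == "A_b_30"
        assert ConditionKey.from_label("A_b_30") == key

    def test_malformed_label_rejected(self):
        with pytest.raises(ValueError):
            ConditionKey.from_label("Ab30")


class TestCombinedModels:
    def test_eighteen_models_six_per_category(self):
        models = enumerate_combined_models()
        assert len(models) == 18
        by_cat = {}
        for m in models:
            by_cat.setdefault(m.category, []).append(m)
        assert {c: len(v) for c, v in by_cat.items()} == {
            "AB_C": 6, "BC_A": 6, "CA_B": 6,
        }

    def test_first_model_keys(self):
        m = enumerate_combined_models()[0]
        assert m.category == "AB_C" and m.model_index == 1
        assert {k.label for k in m.train_keys} == {"A_b_30", "B_a_45"}
        assert m.test_key.label == "C_a_75"

    def test_train_days_match_category_and_test_day_held_out(self):
        for m in enumerate_combined_models():
            train_days = {k.day for k in m.train_keys}
            assert train_days == set(m.category[:2])
            assert m.test_key.day == m.category[-1]

    def test_single_irregular_row_is_flagged(self):
        irregular = [m for m in enumerate_combined_models() if m.irregular]
        assert len(irregular) == 1
        m = irregular[0]
        assert m.category == "CA_B" and m.model_index == 6
        assert [k.label for k in m.train_keys] == ["C_b_75", "A_b_30"]


def _fake_features(
    subjects=("S1",), keys=("A_a_45",), groups=(1, 2, 3), windows=6, seed=0
):
    """Synthetic feature table with linearly separable gesture clusters
    — exercises the evaluation protocol without the signal pipeline."""
    rng = np.random.default_rng(seed)
    gestures = list(sb.GESTURES) + [sb.REST_GESTURE]
    rows = []
    for s in subjects:
        for k in keys:
            day, fat, angle = k.split("_")
            for g in groups:
                for gi, gesture in enumerate(gestures):
                    center = np.zeros(16)
                    center[gi % 16] = 10.0 + gi
                    X = center + 0.1 * rng.standard_normal((windows, 16))
                    for w in range(windows):
                        rows.append(
                            dict(
                                zip(FEATURE_COLUMNS, X[w]),
                                gesture=gesture,
                                subject=s,
                                day=day,
                                fatigue=fat,
                                angle=int(angle),
                                group=g,
                                window=w,
                                key=k,
                            )
                        )
    return pd.DataFrame(rows)


class TestRunPairing:
    def test_repetition_count_and_columns(self):
        feats = _fake_features()
        res = run_pairing(feats, ["A_a_45"], "A_a_45", "lda", n_rep=10, seed=0)
        assert len(res.records) == 10
        assert list(res.records.columns) == RESULT_COLUMNS

    def test_separable_clusters_decode_perfectly(self):
        feats = _fake_features()
        res = run_pairing(feats, ["A_a_45"], "A_a_45", "pnn", n_rep=3, seed=0)
        assert res.mean_accuracy == pytest.approx(1.0)

    def test_identical_seeds_identical_results(self):
        feats = _fake_features()
        a = run_pairing(feats, ["A_a_45"], "A_a_45", "lda", n_rep=4, seed=7)
        b = run_pairing(feats, ["A_a_45"], "A_a_45", "lda", n_rep=4, seed=7)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_single_group_cannot_be_split(self):
        feats = _fake_features(groups=(1,))
        with pytest.raises(ValueError, match="2 groups"):
            run_pairing(feats, ["A_a_45"], "A_a_45", "lda", n_rep=1, seed=0)

    def test_rest_gesture_excluded_from_classification(self):
        feats = _fake_features()
        res = run_pairing(feats, ["A_a_45"], "A_a_45", "lda", n_rep=1, seed=0)
        # perfect accuracy implies an 11-way task; RE windows would be
        # unlabeled-able under the trained model if included
        assert res.mean_accuracy == pytest.approx(1.0)

    def test_group_level_overlap_rejected(self):
        feats = _fake_features()
        sub = feats[feats["group"] == 1]
        with pytest.raises(ValueError, match="overlap"):
            _evaluate_split(sub, sub, "lda", 0.3)


class TestRunCombined:
    def test_points_per_model_without_trimming(self):
        feats = _fake_features(
            subjects=("S1", "S2"),
            keys=[k.label for k in all_condition_keys()],
            groups=(1, 2),
            windows=3,
        )
        res = run_combined(feats, "lda", seed=0, points_per_subject=4)
        counts = res.records.groupby("test_level").size()
        # 2 subjects kept (fewer than 5: no best/worst trimming), 4 points each
        assert set(counts) == {8}
        assert len(counts) == 18

    def test_five_subjects_trimmed_to_thirty_points(self):
        feats = _fake_features(
            subjects=tuple(f"S{i}" for i in range(1, 6)),
            keys=[k.label for k in all_condition_keys()],
            groups=(1, 2),
            windows=2,
        )
        res = run_combined(feats, "lda", seed=0, points_per_subject=10)
        assert res.records["subject"].nunique() == 3
        counts = res.records.groupby("test_level").size()
        assert set(counts) == {30}
        assert len(res.records) == 540


class TestPearsonTrend:
    def _result(self, vectors):
        rows = []
        for subject, vec in vectors.items():
            for i, acc in enumerate(vec):
                rows.append(
                    {
                        "design": "AT",
                        "model_type": "lda",
                        "subject": subject,
                        "train_keys": f"K{i}",
                        "test_key": "T",
                        "train_level": "x",
                        "test_level": "y",
                        "repetition": 0,
                        "accuracy": acc,
                    }
                )
        return ExperimentResult(pd.DataFrame(rows, columns=RESULT_COLUMNS))

    def test_identical_vectors_correlate_perfectly(self):
        res = self._result({"S1": [0.9, 0.8, 0.7], "S2": [0.9, 0.8, 0.7]})
        table = pearson_trend(res)
        assert table["r"].to_numpy() == pytest.approx([1.0, 1.0])

    def test_opposite_trends_correlate_negatively(self):
        res = self._result({"S1": [0.2, 0.5, 0.8], "S2": [0.8, 0.5, 0.2]})
        assert pearson_trend(res)["r"].to_numpy() == pytest.approx([-1.0, -1.0])

    def test_shared_noisy_trend_correlates_strongly(self):
        rng = np.random.default_rng(0)
        trend = np.linspace(0.95, 0.6, 8)
        vecs = {f"S{i}": trend + 0.01 * rng.standard_normal(8) for i in range(4)}
        assert (pearson_trend(self._result(vecs))["r"] > 0.9).all()

    def test_zero_variance_vector_reported_missing(self):
        res = self._result({"S1": [0.5, 0.5, 0.5], "S2": [0.2, 0.5, 0.8]})
        r = pearson_trend(res).set_index("subject")["r"]
        assert np.isnan(r["S1"])


def test_registry_validation_reports_gaps():
    from conftest import generate_conditions

    subjects = sb.make_subjects(1, seed=2)
    keys = [k for k in all_condition_keys() if k.label != "C_b_75"]
    registry = generate_conditions(
        subjects, keys, n_groups=1, seed=2,
        config_kwargs={"duration_a": 0.5, "duration_b": 0.8},
    )
    with pytest.raises(ValueError, match="C_b_75"):
        registry.validate(expected_keys=all_condition_keys())
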