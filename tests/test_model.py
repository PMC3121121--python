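"""Hot-spot labelling, SVM protocol, metrics and significance tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from dbac.model import (HotspotSVM, _inner_f1, evaluate, feature_significance,
                        grid_search, label_hotspots, mann_whitney,
                        nested_loocv)
from dbac.synthetic import make_feature_dataset

COARSE_COSTS = (2.0 ** -1, 2.0 ** 3, 2.0 ** 7)
COARSE_GAMMAS = (2.0 ** -7, 2.0 ** -3, 2.0 ** 1)


class TestLabels:
    def test_threshold_boundary_inclusive(self):
        labels = label_hotspots([2.0, 0.5, 1.99, 3.5])
        assert labels.tolist() == [True, False, False, True]

    def test_missing_ddg_rejected(self):
        with pytest.raises(ValueError):
            label_hotspots([1.0, np.nan])


class TestEvaluate:
    def test_confusion_to_metrics(self):
        rep = evaluate([True] * 43 + [False] * 215,
                       [True] * 29 + [False] * 14 + [True] * 21 + [False] * 194)
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (29, 14, 194, 21)
        assert rep.sensitivity == pytest.approx(0.58)
        assert rep.precision == pytest.approx(0.6744, abs=1e-4)
        assert rep.f1 == pytest.approx(0.6237, abs=1e-4)

    def test_perfect_predictions(self):
        rep = evaluate([True, False, True], [True, False, True])
        assert (rep.sensitivity, rep.precision, rep.specificity,
                rep.accuracy, rep.f1) == (1, 1, 1, 1, 1)

    def test_no_positive_predictions_convention(self):
        rep = evaluate([False, False], [True, False])
        assert rep.precision == 0.0 and rep.f1 == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate([], [])

    @settings(max_examples=100, derandomize=True)
    @given(st_.tuples(*[st_.integers(0, 50)] * 4))
    def test_metric_identities(self, counts):
        tp, fp, tn, fn = counts
        if tp + fp + tn + fn == 0:
            return
        pred = [True] * (tp + fp) + [False] * (fn + tn)
        lab = [True] * tp + [False] * fp + [True] * fn + [False] * tn
        rep = evaluate(pred, lab)
        assert rep.tp + rep.fp + rep.tn + rep.fn == len(pred)
        if rep.precision + rep.sensitivity > 0:
            assert rep.f1 == pytest.approx(
                2 * rep.precision * rep.sensitivity
                / (rep.precision + rep.sensitivity))
        assert 0 <= rep.accuracy <= 1


class TestMannWhitney:
    def test_exact_small_sample(self):
        # all C(6,3)=20 rank splits: the observed split is one of two extremes
        assert mann_whitney([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups(self):
        assert mann_whitney([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_feature_significance_shapes_and_convention(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "flat": np.ones(20),
            "split": np.concatenate([np.arange(10), np.arange(10) + 100.5]),
            "noise": rng.normal(size=20),
        })
        labels = np.array([True] * 10 + [False] * 10)
        with pytest.warns(UserWarning, match="flat"):
            p = feature_significance(df, labels)
        assert list(p.index) == ["flat", "split", "noise"]
        assert p["flat"] == 1.0
        # perfectly separating feature: exact two-sided enumeration value
        from math import comb
        assert p["split"] == pytest.approx(2 / comb(20, 10))


class TestGridSearch:
    def test_separable_clusters_reach_perfect_inner_f1(self):
        x, y = make_feature_dataset(10, 20, separation=8.0, seed=0)
        cost, gamma = grid_search(x, y, COARSE_COSTS, COARSE_GAMMAS, seed=0)
        assert _inner_f1(x.to_numpy(float), y, cost, gamma, seed=0) == 1.0

    def test_identical_rows_fall_back_to_constant_baseline(self):
        x = np.zeros((12, 3))
        y = np.array([True] * 8 + [False] * 4)
        cost, gamma = grid_search(x, y, COARSE_COSTS, COARSE_GAMMAS, seed=0)
        achieved = _inner_f1(x, y, cost, gamma, seed=0)
        # exhaustive constant classifiers on the same folds
        from sklearn.model_selection import StratifiedKFold
        skf = StratifiedKFold(n_splits=4, shuffle=True, random_state=0)
        baselines = []
        for const in (True, False):
            scores = [evaluate([const] * len(te), y[te]).f1
                      for _, te in skf.split(x, y)]
            baselines.append(np.mean(scores))
        assert achieved == pytest.approx(max(baselines))

    def test_single_grid_point_returned(self):
        x, y = make_feature_dataset(5, 5, separation=3.0, seed=1)
        assert grid_search(x, y, costs=(4.0,), gammas=(0.25,)) == (4.0, 0.25)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            grid_search(np.zeros((4, 2)), [True] * 4)


class TestNestedLoocv:
    def test_one_prediction_per_record(self):
        x = np.array([[0.0], [0.1], [5.0], [5.1]])
        y = np.array([False, False, True, True])
        pred, chosen = nested_loocv(x, y, COARSE_COSTS, COARSE_GAMMAS, seed=0)
        assert len(pred) == 4 and len(chosen) == 4

    def test_determinism(self):
        x, y = make_feature_dataset(8, 16, separation=3.0, seed=2)
        a, _ = nested_loocv(x, y, COARSE_COSTS, COARSE_GAMMAS, seed=0)
        b, _ = nested_loocv(x, y, COARSE_COSTS, COARSE_GAMMAS, seed=0)
        np.testing.assert_array_equal(a, b)

    def test_anti_leakage_held_out_label_is_never_read(self):
        x, y = make_feature_dataset(6, 12, separation=3.0, seed=3)
        pred, _ = nested_loocv(x, y, COARSE_COSTS, COARSE_GAMMAS, seed=0)
        for k in (0, 7, 17):
            y_corrupt = y.copy()
            y_corrupt[k] = ~y_corrupt[k]
            pred_c, _ = nested_loocv(x, y_corrupt, COARSE_COSTS,
                                     COARSE_GAMMAS, seed=0)
            assert pred_c[k] == pred[k]

    def test_separable_dataset_recovers_labels(self):
        x, y = make_feature_dataset(15, 45, separation=5.0, seed=0)
        pred, _ = nested_loocv(x, y, COARSE_COSTS, COARSE_GAMMAS, seed=0)
        assert evaluate(pred, y).f1 >= 0.95

    def test_leave_n_out_blocks(self):
        x, y = make_feature_dataset(8, 16, separation=5.0, seed=4)
        pred, _ = nested_loocv(x, y, COARSE_COSTS, COARSE_GAMMAS,
                               seed=0, leave_n=5)
        assert len(pred) == 24 and evaluate(pred, y).f1 >= 0.9


class TestModelResults:
    def test_summary_and_report(self):
        x, y = make_feature_dataset(8, 16, separation=5.0, seed=5)
        ddg = np.where(y, 3.0, 0.5) + np.random.default_rng(0).normal(
            0, 0.1, len(y))
        model = HotspotSVM(x, ddg=ddg, costs=COARSE_COSTS,
                           gammas=COARSE_GAMMAS)
        res = model.fit(seed=0)
        text = res.summary()
        assert "F1" in text and "loocv" in text
        assert res.report.tp + res.report.fp + res.report.tn \
            + res.report.fn == len(y)
        assert 0 <= res.mann_whitney_p <= 1

    def test_labels_follow_threshold(self):
        x = pd.DataFrame(np.zeros((4, 2)))
        m = HotspotSVM(x, ddg=[2.0, 1.99, 5.0, 0.0])
        assert m.labels.tolist() == [True, False, True, False]
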