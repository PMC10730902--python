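"""Fold plans, leakage verification, scalar metrics and ROC/PR machinery."""

import numpy as np
import pandas as pd
import pytest

from circwave.evaluate import (ConfusionCounts, confusion_and_metrics,
                               make_fold_plan, metrics_from_counts,
                               roc_pr_curves, verify_no_leakage)


def subject_manifest(n_per_class=5, scans=2, classes=("normal", "DME", "AMD")):
    rows = []
    for lab in classes:
        for i in range(n_per_class):
            for k in range(scans):
                rows.append({"subject_id": f"{lab}{i}", "label": lab,
                             "scan_index": k})
    return pd.DataFrame(rows)


class TestFoldPlan:
    def test_15_subjects_k5_gives_one_subject_per_class_per_fold(self):
        plan = make_fold_plan(subject_manifest(5), K=5, seed=0)
        for test in plan.outer_test:
            assert len(test) == 3
            labels = {s.rstrip("0123456789") for s in test}
            assert labels == {"normal", "DME", "AMD"}

    def test_outer_tests_partition_subjects(self):
        manifest = subject_manifest(6)
        plan = make_fold_plan(manifest, K=5, seed=3)
        flat = [s for f in plan.outer_test for s in f]
        assert len(flat) == len(set(flat)) == 18
        assert set(flat) == set(manifest["subject_id"])

    def test_every_generated_plan_passes_leakage_check(self):
        for seed in range(5):
            manifest = subject_manifest(5)
            plan = make_fold_plan(manifest, K=5, seed=seed)
            assert verify_no_leakage(plan, manifest).ok

    def test_stratification_within_one_subject(self):
        manifest = subject_manifest(7)
        plan = make_fold_plan(manifest, K=5, seed=1)
        for test in plan.outer_test:
            per_class = {}
            for s in test:
                per_class[s.rstrip("0123456789")] = per_class.get(
                    s.rstrip("0123456789"), 0) + 1
            assert max(per_class.values()) - min(per_class.values()) <= 1

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            make_fold_plan(subject_manifest(3), K=5)

    def test_corrupted_plan_fails_with_named_subject(self):
        manifest = subject_manifest(5)
        plan = make_fold_plan(manifest, K=5, seed=0)
        leaked = plan.outer_test[0][0]
        plan.inner[0][0]["train"].append(leaked)  # test subject on train side
        report = verify_no_leakage(plan, manifest)
        assert not report.ok
        assert any(leaked in v for v in report.violations)

    def test_empty_fold_fails(self):
        manifest = subject_manifest(5)
        plan = make_fold_plan(manifest, K=5, seed=0)
        plan.outer_test[2] = []
        assert not verify_no_leakage(plan, manifest).ok


class TestScalarMetrics:
    def test_hand_built_counts_match_formula_substitution(self):
        cc = ConfusionCounts(TP=8, FN=2, TN=9, FP=1, cls="DME")
        m = metrics_from_counts(cc)
        assert m["SE"] == pytest.approx(0.8)
        assert m["SP"] == pytest.approx(0.9)
        assert m["PR"] == pytest.approx(8 / 9)
        assert m["ACC"] == pytest.approx(0.85)
        assert m["F1"] == pytest.approx(16 / 19)

    def test_perfect_prediction_gives_all_ones(self):
        y = ["a", "b", "c", "a", "b", "c"]
        _, rep = confusion_and_metrics(y, y, ["a", "b", "c"])
        for m in ("ACC", "SE", "SP", "PR", "F1"):
            assert rep["macro"][m] == 1.0

    def test_all_wrong_binary_prediction(self):
        y_true = ["pos", "neg"] * 5
        y_pred = ["neg", "pos"] * 5
        _, rep = confusion_and_metrics(y_true, y_pred, ["pos", "neg"])
        assert rep["per_class"]["pos"]["SE"] == 0.0
        assert rep["per_class"]["pos"]["SP"] == 0.0

    def test_one_vs_rest_counts_consistent_with_matrix(self):
        rng = np.random.default_rng(0)
        classes = ["a", "b", "c"]
        y_true = rng.choice(classes, 60)
        y_pred = rng.choice(classes, 60)
        counts, rep = confusion_and_metrics(y_true, y_pred, classes)
        assert rep["confusion"].sum() == 60
        for i, c in enumerate(classes):
            assert counts[c].total == 60
            assert counts[c].TP == rep["confusion"][i, i]
            assert rep["confusion"][i].sum() == (y_true == c).sum()

    def test_macro_metrics_invariant_under_relabeling(self):
        rng = np.random.default_rng(1)
        classes = ["a", "b", "c"]
        y_true = rng.choice(classes, 50)
        y_pred = rng.choice(classes, 50)
        _, rep1 = confusion_and_metrics(y_true, y_pred, classes)
        swap = {"a": "c", "b": "a", "c": "b"}
        y_true2 = [swap[y] for y in y_true]
        y_pred2 = [swap[y] for y in y_pred]
        _, rep2 = confusion_and_metrics(y_true2, y_pred2, classes)
        for m in ("ACC", "SE", "SP", "PR", "F1"):
            assert rep1["macro"][m] == pytest.approx(rep2["macro"][m])

    def test_zero_denominator_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="zero denominator"):
            m = metrics_from_counts(ConfusionCounts(TP=0, FN=0, TN=5, FP=0,
                                                    cls="x"))
        assert m["SE"] == 0.0


class TestCurves:
    def test_perfect_scores_give_unit_areas(self):
        y = np.array(["a", "b", "c", "a", "b", "c"])
        scores = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]] * 2, float)
        curves = roc_pr_curves(y, scores, ["a", "b", "c"])
        assert curves["macro_ROAUC"] == pytest.approx(1.0)
        assert curves["macro_PRAUC"] == pytest.approx(1.0)

    def test_constant_scores_give_chance_roc(self):
        rng = np.random.default_rng(0)
        y = rng.choice(["a", "b"], 100)
        scores = np.full((100, 2), 0.5)
        curves = roc_pr_curves(y, scores, ["a", "b"])
        assert curves["macro_ROAUC"] == pytest.approx(0.5)

    def test_random_scores_near_chance(self):
        rng = np.random.default_rng(0)
        y = rng.choice(["a", "b"], 200)
        scores = rng.random((200, 2))
        curves = roc_pr_curves(y, scores, ["a", "b"])
        assert 0.4 <= curves["macro_ROAUC"] <= 0.6

    def test_areas_match_sklearn_oracle(self):
        """Independent cross-check of the hand-rolled threshold sweep."""
        from sklearn.metrics import average_precision_score, roc_auc_score

        rng = np.random.default_rng(5)
        y = rng.choice(["a", "b", "c"], 120)
        scores = rng.random((120, 3)) + 0.5 * (y[:, None] ==
                                               np.array(["a", "b", "c"]))
        curves = roc_pr_curves(y, scores, ["a", "b", "c"])
        for i, c in enumerate(["a", "b", "c"]):
            yb = (y == c).astype(int)
            assert curves["per_class"][c]["ROAUC"] == pytest.approx(
                roc_auc_score(yb, scores[:, i]), abs=1e-10)
            assert curves["per_class"][c]["PRAUC"] == pytest.approx(
                average_precision_score(yb, scores[:, i]), abs=1e-10)

    def test_absent_class_skipped_with_warning(self):
        y = np.array(["a", "a", "b", "b"])
        scores = np.random.default_rng(0).random((4, 3))
        with pytest.warns(UserWarning, match="absent"):
            curves = roc_pr_curves(y, scores, ["a", "b", "c"])
        assert "c" not in curves["per_class"]

    def test_misaligned_scores_rejected(self):
        with pytest.raises(ValueError):
            roc_pr_curves(["a", "b"], np.zeros((3, 2)), ["a", "b"])
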