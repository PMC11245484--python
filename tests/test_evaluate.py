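"""Metrics, majority voting, cross-validation runner and cohort statistics."""

import numpy as np
import pandas as pd
import pytest

from ppgfatigue.dataset import Window, make_folds
from ppgfatigue.evaluate import (
    class_metrics,
    cohort_stats,
    confusion_matrix,
    error_metrics,
    gate,
    grid_sweep,
    majority_vote,
    roc_auc,
    run_cv,
)
from ppgfatigue.models import ModelConfig
from ppgfatigue.reference import reference_cohort

F, N = "fatigue", "non_fatigue"


def sweep_auc_oracle(scores, labels):
    """Trapezoidal ROC integration over every threshold (independent oracle)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    thresholds = np.concatenate([[np.inf], np.sort(np.unique(scores))[::-1], [-np.inf]])
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    tpr = [np.sum((scores >= t) & (labels == 1)) / n_pos for t in thresholds]
    fpr = [np.sum((scores >= t) & (labels == 0)) / n_neg for t in thresholds]
    return float(np.trapezoid(tpr, fpr))


class TestConfusionMatrix:
    def test_counts_example(self):
        conf = confusion_matrix([F, F, F, N, N], [F, F, N, N, F])
        assert conf.tolist() == [[2, 1], [1, 1]]
        assert conf.sum() == 5

    def test_perfect_predictions_have_empty_off_diagonal(self):
        conf = confusion_matrix([F, N, F], [F, N, F])
        assert conf[0, 1] == 0 and conf[1, 0] == 0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="class set"):
            confusion_matrix([F, "drowsy"], [F, N])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([F, N], [F])


class TestClassMetrics:
    def test_equal_precision_recall_gives_equal_f1(self):
        # Pr = Re = 0.8 -> harmonic mean is 0.8
        conf = np.array([[8, 2], [2, 8]])
        m = class_metrics(conf)
        assert m["precision"] == pytest.approx(0.8)
        assert m["recall"] == pytest.approx(0.8)
        assert m["f1"] == pytest.approx(0.8)

    def test_small_example_values(self):
        m = class_metrics(np.array([[2, 1], [1, 1]]))
        assert m["accuracy"] == pytest.approx(0.6)
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["recall"] == pytest.approx(2 / 3)
        assert m["f1"] == pytest.approx(2 / 3)

    def test_zero_recall_collapses_f1(self):
        with pytest.warns(UserWarning):
            m = class_metrics(np.array([[0, 3], [0, 7]]))
        assert m["recall"] == 0.0
        assert m["f1"] == 0.0

    def test_f1_between_min_and_arithmetic_mean(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            conf = rng.integers(1, 30, size=(2, 2))
            m = class_metrics(conf)
            pr, re = m["precision"], m["recall"]
            if pr > 0 and re > 0:
                assert min(pr, re) - 1e-12 <= m["f1"] <= np.sqrt(pr * re) + 1e-12
                assert m["f1"] <= (pr + re) / 2 + 1e-12

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            class_metrics(np.zeros((2, 2), dtype=int))


class TestErrorMetrics:
    def test_unit_errors(self):
        m = error_metrics([1.0, -1.0, 1.0, -1.0], [0.0, 0.0, 0.0, 0.0])
        assert (m["mae"], m["mse"], m["rmse"]) == (1.0, 1.0, 1.0)

    def test_mixed_errors(self):
        m = error_metrics([3.0, -1.0], [0.0, 0.0])
        assert m["mae"] == pytest.approx(2.0)
        assert m["mse"] == pytest.approx(5.0)
        assert m["rmse"] == pytest.approx(np.sqrt(5.0))

    def test_identical_vectors_have_zero_error(self):
        m = error_metrics([0.2, 0.8], [0.2, 0.8])
        assert m["mae"] == m["mse"] == m["rmse"] == 0.0

    def test_mse_is_rmse_squared(self):
        rng = np.random.default_rng(1)
        m = error_metrics(rng.random(100), rng.random(100))
        assert m["mse"] == pytest.approx(m["rmse"] ** 2, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            error_metrics([1.0], [1.0, 2.0])


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_constant_scores_give_chance_level(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_rank_formulation_matches_threshold_sweep_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(10, 60))
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0], labels[1] = 0, 1
            scores = np.round(rng.random(n), 2)  # induces ties
            assert roc_auc(scores, labels) == pytest.approx(
                sweep_auc_oracle(scores, labels), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestMajorityVote:
    def test_narrow_majority_wins(self):
        assert majority_vote([F] * 21 + [N] * 19) == F

    def test_unanimous_non_fatigue(self):
        assert majority_vote([N] * 10) == N

    def test_exact_tie_resolves_to_fatigue(self):
        assert majority_vote([F] * 20 + [N] * 20) == F

    def test_empty_vote_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([])


class TestGate:
    def _metrics(self, **overrides):
        m = {"auc": 0.9, "f1": 0.9, "precision": 0.9, "accuracy": 0.9}
        m.update(overrides)
        return m

    def test_all_metrics_high_passes(self):
        assert gate(self._metrics()) is True

    def test_boundary_value_fails_strict_inequality(self):
        assert gate(self._metrics(auc=0.825)) is False

    def test_one_weak_metric_fails(self):
        assert gate(self._metrics(f1=0.5)) is False

    def test_missing_metric_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            gate({"auc": 0.9, "f1": 0.9, "precision": 0.9})


class TestCohortStats:
    def test_reference_cohort_means(self):
        stats = cohort_stats(reference_cohort())
        assert round(stats.kss_mean[F], 1) == 7.4
        assert round(stats.pvt_mean[F], 1) == 469.4
        assert round(stats.kss_mean[N], 1) == 2.8
        assert round(stats.pvt_mean[N]) == 356

    def test_fatigue_kss_population_std(self):
        stats = cohort_stats(reference_cohort())
        assert round(stats.kss_sd[F], 1) == 0.6

    def test_single_element_groups_have_zero_std(self):
        df = pd.DataFrame(
            {"condition": [F, N], "kss": [7, 3], "pvt_ms": [400.0, 300.0]}
        )
        stats = cohort_stats(df)
        assert stats.kss_sd[F] == 0.0 and stats.pvt_sd[N] == 0.0

    def test_missing_condition_rejected(self):
        df = pd.DataFrame({"condition": [F], "kss": [7], "pvt_ms": [400.0]})
        with pytest.raises(ValueError, match="non_fatigue"):
            cohort_stats(df)

    def test_accepts_profiles(self):
        from ppgfatigue.synth import SubjectProfile

        profiles = [
            SubjectProfile("S01", F, 7, 469.0, 0.8, 0.02, 0.1),
            SubjectProfile("S01", N, 3, 356.0, 0.8, 0.05, 0.3),
        ]
        stats = cohort_stats(profiles)
        assert stats.kss_mean[F] == 7.0

    def test_summary_frame_has_one_decimal_format(self):
        frame = cohort_stats(reference_cohort()).to_frame()
        assert frame.loc[frame.condition == F, "kss"].item().startswith("7.4 ±")


def _random_windows(rng, n_subjects=6, per_subject=10, n=64):
    """Featureless windows with coin-flip labels: no class signal at all."""
    windows = []
    for s in range(n_subjects):
        for i in range(per_subject):
            label = F if rng.random() < 0.5 else N
            windows.append(
                Window(f"S{s:02d}", i, rng.standard_normal(n), "ppg", label)
            )
    # run_cv needs both classes in every training split; coin flips at this
    # size virtually guarantee it, but re-draw defensively if not
    return windows


TINY_MODEL = ModelConfig(
    layers=4, kernels=3, kernel_size=5, bilstm_hidden=4,
    total_stride=8, epochs=4, batch_size=16, seed=0,
)


class TestRunCv:
    def test_null_labels_give_chance_level_accuracy(self):
        rng = np.random.default_rng(123)
        windows = _random_windows(rng)
        plan = make_folds(sorted({w.subject_id for w in windows}), "kfold_by_subject", k=3, seed=0)
        report = run_cv(windows, TINY_MODEL, plan)
        n = int(report.pooled_confusion.sum())
        se = 0.5 / np.sqrt(n)
        assert abs(report.metrics["accuracy"] - 0.5) < 3 * se

    def test_report_internal_consistency(self):
        rng = np.random.default_rng(5)
        windows = _random_windows(rng, n_subjects=4, per_subject=8)
        plan = make_folds(sorted({w.subject_id for w in windows}), "leave_one_subject_out")
        report = run_cv(windows, TINY_MODEL, plan)
        # confusion conservation and the MSE = RMSE^2 identity
        assert int(report.pooled_confusion.sum()) == len(windows)
        assert sum(int(c.sum()) for c in report.fold_confusions) == len(windows)
        assert report.metrics["mse"] == pytest.approx(report.metrics["rmse"] ** 2, abs=1e-12)
        recomputed = class_metrics(report.pooled_confusion)
        assert report.metrics["accuracy"] == pytest.approx(recomputed["accuracy"], abs=1e-12)
        assert set(report.subject_votes.subject_id) == {w.subject_id for w in windows}

    def test_windows_outside_plan_rejected(self):
        rng = np.random.default_rng(5)
        windows = _random_windows(rng, n_subjects=3, per_subject=4)
        plan = make_folds(["S00", "S01"], "leave_one_subject_out")
        with pytest.raises(ValueError, match="missing from the plan"):
            run_cv(windows, TINY_MODEL, plan)


class TestGridSweep:
    def test_one_report_row_per_setting_reproducibly(self):
        rng = np.random.default_rng(9)
        windows = _random_windows(rng, n_subjects=4, per_subject=6)
        plan = make_folds(sorted({w.subject_id for w in windows}), "kfold_by_subject", k=2, seed=0)
        grid = [{"layers": 4, "kernels": 3}, {"layers": 6, "kernels": 4}]
        table1, reports = grid_sweep("resnet_bilstm", grid, windows, plan, TINY_MODEL)
        table2, _ = grid_sweep("resnet_bilstm", grid, windows, plan, TINY_MODEL)
        assert len(table1) == len(reports) == 2
        assert table1.accuracy.tolist() == table2.accuracy.tolist()
        best = table1[table1.best]
        assert (best.accuracy.iloc[0] >= table1.accuracy).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            grid_sweep("resnet_bilstm", [], [], None, TINY_MODEL)
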