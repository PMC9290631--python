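"""Fisher scoring, leak-free LOOCV selection, and the classifier report."""

import numpy as np
import pytest

from conftest import ToyTable
from gmshore.selection import (
    ClassifierReport,
    cost_grid,
    final_report,
    fisher_scores,
    optimize_cost,
    run_selection,
    step1_accuracy_curve,
    step2_select_n_opt,
    step3_consensus,
    train_linear_svm,
)


class TestFisherScores:
    def test_worked_example(self):
        """{0,1} vs {10,11}: numerator 100, denominator 2, score 50."""
        x = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array(["A", "A", "B", "B"])
        assert fisher_scores(x, y)[0] == pytest.approx(50.0, rel=1e-12)

    def test_uninformative_feature_scores_zero(self):
        x = np.array([[1.0, 5.0], [2.0, 5.0], [1.0, 5.0], [2.0, 5.0]])
        y = np.array(["A", "A", "B", "B"])
        assert fisher_scores(x, y)[1] == 0.0

    def test_constant_within_class_distinct_means_is_inf(self):
        x = np.array([[1.0], [1.0], [2.0], [2.0]])
        y = np.array(["A", "A", "B", "B"])
        assert np.isinf(fisher_scores(x, y)[0])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((20, 7))
        y = np.array(["A", "B"] * 10)
        perm = rng.permutation(20)
        assert np.allclose(fisher_scores(x, y), fisher_scores(x[perm], y[perm]),
                           rtol=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="class"):
            fisher_scores(np.ones((4, 2)), np.array(["A"] * 4))


class TestTrainLinearSvm:
    def test_separable_training_accuracy(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((20, 2))
        y = np.where(x[:, 0] > 0, "RRMS", "PPMS")
        model = train_linear_svm(x, y, cost=100.0)
        assert np.mean(model.predict(x) == y) == 1.0

    def test_duplicated_feature_column_same_predictions(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((16, 1))
        y = np.array(["PPMS", "RRMS"] * 8)
        xt = rng.standard_normal((8, 1))
        single = train_linear_svm(x, y, cost=1.0).predict(xt)
        double = train_linear_svm(np.hstack([x, x]), y, cost=1.0).predict(
            np.hstack([xt, xt]))
        assert np.array_equal(single, double)

    def test_label_flip_negates_decision(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((14, 3))
        y = np.array(["PPMS", "RRMS"] * 7)
        y_flip = np.where(y == "PPMS", "RRMS", "PPMS")
        d1 = train_linear_svm(x, y, cost=1.0).decision(x)
        d2 = train_linear_svm(x, y_flip, cost=1.0).decision(x)
        # SMO converges to a solver tolerance, not machine precision
        assert np.allclose(d1, -d2, atol=1e-3)
        assert np.all(np.sign(d1) == -np.sign(d2))

    def test_zero_variance_feature_warns(self):
        x = np.column_stack([np.arange(8.0), np.full(8, 3.0)])
        y = np.array(["PPMS", "RRMS"] * 4)
        with pytest.warns(UserWarning, match="zero-variance"):
            train_linear_svm(x, y, cost=1.0)

    def test_invalid_cost(self):
        with pytest.raises(ValueError, match="cost"):
            train_linear_svm(np.ones((4, 1)), np.array(["A", "B", "A", "B"]), cost=0.0)


class TestStep1:
    def test_full_sweep_equals_plain_loocv_at_n_max(self, toy_table):
        """At n = N selection is vacuous: accuracy equals all-feature LOOCV."""
        res = step1_accuracy_curve(toy_table, cost=1.0)
        # independent plain LOOCV with all features
        x, y = toy_table.x, toy_table.y
        correct = []
        for i in range(len(y)):
            tr = np.delete(np.arange(len(y)), i)
            model = train_linear_svm(x[tr], y[tr], cost=1.0)
            correct.append(float(model.predict(x[[i]])[0] == y[i]))
        assert res.accuracy[-1] == pytest.approx(np.mean(correct), rel=1e-12)

    def test_perfect_feature_dominates(self, toy_table):
        """The separating feature is ranked first: curve is 1.0 for all n."""
        res = step1_accuracy_curve(toy_table, cost=1.0)
        assert np.all(res.accuracy == 1.0)
        assert np.all(res.rankings[:, 0] == 2)

    def test_rankings_independent_of_cap(self, toy_table):
        full = step1_accuracy_curve(toy_table, cost=1.0)
        capped = step1_accuracy_curve(toy_table, cost=1.0, n_max=2)
        assert np.array_equal(full.rankings, capped.rankings)
        assert capped.accuracy.size == 2

    def test_no_leakage_from_held_out_row(self, toy_table):
        """Corrupting the held-out subject cannot change that fold's ranking."""
        res = step1_accuracy_curve(toy_table, cost=1.0, n_max=1)
        x = toy_table.x.copy()
        x[4] = 1e6
        corrupted = ToyTable(x, toy_table.y)
        res2 = step1_accuracy_curve(corrupted, cost=1.0, n_max=1)
        assert np.array_equal(res.rankings[4], res2.rankings[4])

    def test_chance_accuracy_on_null_table(self):
        """Noise features, balanced labels: mean LOOCV accuracy near 0.5."""
        rng = np.random.default_rng(77)
        table = ToyTable(rng.standard_normal((30, 50)), np.array(["PPMS", "RRMS"] * 15))
        res = step1_accuracy_curve(table, cost=0.4662, n_max=10)
        assert res.accuracy.mean() < 0.75

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="4 subjects"):
            step1_accuracy_curve(ToyTable(np.ones((3, 2)),
                                          np.array(["A", "B", "A"])), cost=1.0)


class TestStep2:
    def test_worked_trace(self):
        """acc=[.6,.7,.7], var=[.01,.02,.005]: n=2 rejected, n=3 accepted."""
        assert step2_select_n_opt([0.6, 0.7, 0.7], [0.01, 0.02, 0.005]) == 3

    def test_constant_curves_take_last(self):
        assert step2_select_n_opt([0.7] * 5, [0.01] * 5) == 5

    def test_single_point(self):
        assert step2_select_n_opt([0.9], [0.0]) == 1

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            step2_select_n_opt([], [])

    def test_strictly_better_always_updates(self):
        assert step2_select_n_opt([0.5, 0.9, 0.6], [0.02, 0.01, 0.0]) == 2


class TestStep3:
    def test_identical_rankings(self):
        rankings = np.tile(np.array([3, 1, 0, 2]), (5, 1))
        names = ["a", "b", "c", "d"]
        selected, counts = step3_consensus(rankings, 2, names)
        assert selected == ["d", "b"]
        assert counts == {"d": 5, "b": 5, "a": 0, "c": 0}

    def test_count_ordering(self):
        # feature 0 in top-1 of 4/5 folds; feature 1 in 1/5
        rankings = np.array([[0, 1, 2], [0, 1, 2], [0, 1, 2], [0, 2, 1], [1, 0, 2]])
        selected, counts = step3_consensus(rankings, 1, ["x", "y", "z"])
        assert selected == ["x"]
        assert counts["x"] == 4 and counts["y"] == 1

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(6)
        n_feat, n_folds, n_opt = 8, 4, 3
        rankings = np.vstack([rng.permutation(n_feat) for _ in range(n_folds)])
        names = [f"f{i}" for i in range(n_feat)]
        _, counts = step3_consensus(rankings, n_opt, names)
        brute = {name: 0 for name in names}
        for fold in range(n_folds):
            for pos in range(n_opt):
                brute[names[rankings[fold, pos]]] += 1
        assert counts == brute

    def test_n_opt_out_of_range(self):
        with pytest.raises(ValueError, match="n_opt"):
            step3_consensus(np.array([[0, 1]]), 3, ["a", "b"])


class TestCostGrid:
    def test_grid_definition(self):
        grid = cost_grid()
        assert grid.size == 100
        assert grid[0] == 0.0005 and grid[-1] == 512.0
        spacing = np.diff(grid)
        assert np.all(np.abs(spacing - (512.0 - 0.0005) / 99) < 1e-12)

    def test_tie_takes_smallest_cost(self, toy_table):
        """When accuracy is constant over the scanned costs, the smallest wins.

        (The scan starts at moderate costs: at C ~ 5e-4 a leave-one-out
        fold's class imbalance drives the SVM to the majority class, so
        accuracy is genuinely cost-dependent at the extreme low end.)
        """
        grid = np.array([1.0, 10.0, 100.0])
        from gmshore.selection import _loocv_outcomes

        accs = [_loocv_outcomes(toy_table.x, toy_table.y, c)[0].mean() for c in grid]
        assert len(set(accs)) == 1  # constant over this grid
        assert optimize_cost(toy_table, grid=grid) == 1.0

    def test_agrees_with_exhaustive_scan(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal((16, 3))
        y = np.array(["PPMS", "RRMS"] * 8)
        x[:, 0] += np.where(y == "RRMS", 0.8, -0.8)
        table = ToyTable(x, y)
        grid = np.array([0.001, 0.1, 1.0, 10.0])
        from gmshore.selection import _loocv_outcomes

        accs = [_loocv_outcomes(table.x, table.y, c)[0].mean() for c in grid]
        expected = grid[int(np.argmax(accs))]
        assert optimize_cost(table, grid=grid) == expected


class TestClassifierReport:
    def test_published_confusion_arithmetic(self):
        """31/45 and 32/45 correct: accuracy 70%, precision 32/46."""
        report = ClassifierReport.from_confusion([[31, 14], [13, 32]])
        assert report.accuracy == pytest.approx(63 / 90, rel=1e-12)
        assert report.accuracy == pytest.approx(0.70, rel=1e-12)
        assert report.precision == pytest.approx(32 / 46, rel=1e-12)
        assert report.sensitivity == pytest.approx(32 / 45, rel=1e-12)
        assert report.specificity == pytest.approx(31 / 45, rel=1e-12)

    def test_metrics_consistent_with_matrix(self):
        rng = np.random.default_rng(3)
        conf = rng.integers(1, 30, (2, 2))
        r = ClassifierReport.from_confusion(conf)
        tn, fp = conf[0]
        fn, tp = conf[1]
        assert abs(r.accuracy - (tn + tp) / conf.sum()) < 1e-12
        assert abs(r.precision - tp / (tp + fp)) < 1e-12

    def test_perfect_toy_report(self, toy_table):
        report = final_report(toy_table, ["f2"], cost=1.0)
        assert report.accuracy == 1.0
        assert report.auc == 1.0
        assert report.sensitivity == 1.0 and report.specificity == 1.0
        assert report.confusion.sum() == len(toy_table)

    def test_requires_features(self, toy_table):
        with pytest.raises(ValueError, match="at least one"):
            final_report(toy_table, [])
        with pytest.raises(ValueError, match="absent"):
            final_report(toy_table, ["nope"])


class TestRunSelection:
    def test_deterministic(self, toy_table):
        r1, rep1 = run_selection(toy_table, cost=1.0)
        r2, rep2 = run_selection(toy_table, cost=1.0)
        assert np.array_equal(r1.rankings, r2.rankings)
        assert r1.selected == r2.selected
        assert np.array_equal(rep1.confusion, rep2.confusion)

    def test_replicated_accounting(self, toy_table):
        res, _ = run_selection(toy_table, cost=1.0)
        n = res.accuracy.size
        replicated = res.occurrence_counts_replicated()
        assert all(replicated[k] == v * n for k, v in res.occurrence_counts.items())
        assert res.n_models == res.rankings.shape[0] * n
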