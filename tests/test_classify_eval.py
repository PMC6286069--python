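"""Split plan, classifiers, tuning, ROC cutoffs, metrics, rank test."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

import oxiwave as ow
from oxiwave.classify_eval import ModelSpec, _cv_accuracy, make_classifier


def _toy_separable(n=40, seed=0, gap=3.0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, 2))
    X[:, 0] += gap * y
    return X, y


class TestMakeSplit:
    def test_stratified_proportions(self):
        y = np.r_[np.ones(40, int), np.zeros(60, int)]
        plan = ow.make_split(y, seed=4)
        assert len(plan.optimization_idx) == 60
        assert len(plan.crossval_idx) == 40
        assert abs(y[plan.optimization_idx].sum() - 24) <= 1
        assert abs(y[plan.crossval_idx].sum() - 16) <= 1
        # disjoint and exhaustive
        assert not set(plan.optimization_idx) & set(plan.crossval_idx)
        assert len(plan.optimization_idx) + len(plan.crossval_idx) == 100

    def test_deterministic(self):
        y = np.r_[np.ones(40, int), np.zeros(60, int)]
        a, b = ow.make_split(y, seed=7), ow.make_split(y, seed=7)
        np.testing.assert_array_equal(a.optimization_idx, b.optimization_idx)
        for (ta, ea), (tb, eb) in zip(a.folds, b.folds):
            np.testing.assert_array_equal(ta, tb)
            np.testing.assert_array_equal(ea, eb)

    def test_fold_sizes(self):
        y = np.repeat([0, 1], 50)
        plan = ow.make_split(y, seed=1)
        assert sorted(len(te) for _, te in plan.folds) == [8, 8, 8, 8, 8]
        # each fold's classes are balanced within one subject
        for _, te in plan.folds:
            assert abs(y[te].sum() - 4) <= 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ow.make_split(np.zeros(30, int), seed=0)


class TestTrainModel:
    @pytest.mark.parametrize("kind", ["lr", "svm", "mlp"])
    def test_separable_toy_perfect_training_accuracy(self, kind):
        X, y = _toy_separable(gap=5.0)
        model = ow.train_model(ModelSpec(kind, seed=0), X, y)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_lr_symmetric_toy_zero_intercept(self):
        rng = np.random.default_rng(2)
        half = rng.normal(size=(30, 2)) + [2.0, 0.0]
        X = np.vstack([half, -half])
        y = np.r_[np.ones(30, int), np.zeros(30, int)]
        model = ow.train_model(ModelSpec("lr"), X, y)
        assert model["model"].intercept_[0] == pytest.approx(0.0, abs=1e-6)

    def test_lr_matches_irls_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 2))
        # noisy (non-separable) labels so the ML optimum is finite
        logits = 1.2 * X[:, 0] - 0.7 * X[:, 1] + 0.3
        y = (rng.random(60) < 1.0 / (1.0 + np.exp(-logits))).astype(int)
        model = ow.train_model(ModelSpec("lr"), X, y)
        # oracle: iteratively reweighted least squares on z-scored design
        Z = (X - X.mean(0)) / X.std(0)
        A = np.c_[np.ones(len(Z)), Z]
        beta = np.zeros(3)
        for _ in range(100):
            p = 1.0 / (1.0 + np.exp(-A @ beta))
            w = p * (1.0 - p)
            grad = A.T @ (y - p)
            hess = A.T @ (A * w[:, None])
            step = np.linalg.solve(hess, grad)
            beta = beta + step
            if np.abs(step).max() < 1e-12:
                break
        est = model["model"]
        assert est.intercept_[0] == pytest.approx(beta[0], abs=1e-6)
        np.testing.assert_allclose(est.coef_[0], beta[1:], atol=1e-6)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError):
            ow.train_model(ModelSpec("lr"), X, np.zeros(10, int))


class TestTuneHyperparams:
    def test_grid_of_one(self):
        X, y = _toy_separable()
        out = ow.tune_hyperparams("svm", X, y, seed=0, c_grid=(0.5,), n_folds=4)
        assert out == {"c": 0.5}

    def test_selected_c_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(5)
        n = 60
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 4))
        X[:, 0] += 1.0 * y  # weak signal, noisy extras
        grid = (1e-3, 1e-1, 1e1)
        out = ow.tune_hyperparams("svm", X, y, seed=11, c_grid=grid, n_folds=5)
        # oracle: evaluate the same folds exhaustively with raw sklearn
        skf = StratifiedKFold(5, shuffle=True, random_state=11)
        accs = {}
        for c in grid:
            fold_accs = []
            for tr, te in skf.split(X, y):
                mu, sd = X[tr].mean(0), X[tr].std(0)
                m = SVC(kernel="linear", C=c).fit((X[tr] - mu) / sd, y[tr])
                fold_accs.append(np.mean(m.predict((X[te] - mu) / sd) == y[te]))
            accs[c] = np.mean(fold_accs)
        best = max(sorted(grid), key=lambda c: (accs[c], -c))
        assert out["c"] == best

    def test_mlp_grid_allows_unregularized(self):
        X, y = _toy_separable(n=30)
        out = ow.tune_hyperparams(
            "mlp",
            X,
            y,
            seed=0,
            nh_grid=(2,),
            alpha_grid=(0.0,),
            n_folds=3,
            n_runs=2,
        )
        assert out == {"n_hidden": 2, "alpha": 0.0}

    def test_empty_grid_rejected(self):
        X, y = _toy_separable()
        with pytest.raises(ValueError, match="grid"):
            ow.tune_hyperparams("svm", X, y, c_grid=())


class TestRocCutoff:
    def test_perfect_separation_midpoint(self):
        scores = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        labels = np.array([0, 0, 0, 1, 1, 1])
        t = ow.roc_optimal_cutoff(scores, labels)
        assert 0.3 < t < 0.7
        assert t == pytest.approx(0.5)

    def test_degenerate_identical_scores(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            t = ow.roc_optimal_cutoff(np.full(6, 2.0), np.array([0, 1, 0, 1, 0, 1]))
        assert t == 2.0

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=6)
        labels = np.array([0, 1, 0, 1, 1, 0])
        t = ow.roc_optimal_cutoff(scores, labels)
        # oracle: scan a dense grid of thresholds
        grid = np.linspace(scores.min() - 1, scores.max() + 1, 4001)
        best_j = -np.inf
        for g in grid:
            pred = scores >= g
            se = (pred & (labels == 1)).sum() / 3
            sp = (~pred & (labels == 0)).sum() / 3
            best_j = max(best_j, se + sp - 1)
        pred = scores >= t
        se = (pred & (labels == 1)).sum() / 3
        sp = (~pred & (labels == 0)).sum() / 3
        assert se + sp - 1 == pytest.approx(best_j)


class TestDiagnosticMetrics:
    def test_hand_arithmetic_2x2(self):
        # TP=9, FN=1, TN=9, FP=1
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        pred = y.copy()
        pred[0] = 0  # one miss
        pred[10] = 1  # one false alarm
        m = ow.diagnostic_metrics(pred, y)
        assert m.se == pytest.approx(90.0)
        assert m.sp == pytest.approx(90.0)
        assert m.ppv == pytest.approx(90.0)
        assert m.npv == pytest.approx(90.0)
        assert m.acc == pytest.approx(90.0)
        assert m.lr_plus == pytest.approx(9.0)
        assert m.lr_minus == pytest.approx(1.0 / 9.0)

    def test_perfect_prediction_infinite_lr(self):
        y = np.array([0, 0, 1, 1])
        m = ow.diagnostic_metrics(y, y)
        assert m.se == 100.0 and m.sp == 100.0 and m.acc == 100.0
        assert np.isinf(m.lr_plus) and m.degenerate

    def test_all_positive_prediction(self):
        y = np.array([0, 1, 0, 1])
        m = ow.diagnostic_metrics(np.ones(4, int), y)
        assert m.se == 100.0 and m.sp == 0.0

    def test_acc_is_prevalence_weighted_se_sp(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            y = rng.integers(0, 2, 30)
            if np.unique(y).size < 2:
                continue
            pred = rng.integers(0, 2, 30)
            m = ow.diagnostic_metrics(pred, y)
            prev = y.mean()
            assert m.acc == pytest.approx(prev * m.se + (1 - prev) * m.sp)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ow.diagnostic_metrics(np.array([]), np.array([]))


class TestKfoldEvaluate:
    def test_deterministic_repeat(self):
        X, y = _toy_separable(n=60, gap=1.0)
        plan = ow.make_split(y, seed=3)
        model = make_classifier(ModelSpec("lr"))
        a = ow.kfold_evaluate(plan, model, X, y)
        b = ow.kfold_evaluate(plan, model, X, y)
        assert a.mean() == b.mean()

    def test_separable_cohort_perfect(self):
        X, y = _toy_separable(n=60, gap=6.0)
        plan = ow.make_split(y, seed=3)
        rep = ow.kfold_evaluate(plan, make_classifier(ModelSpec("svm", c=1.0)), X, y)
        assert rep.mean()["acc"] == 100.0

    def test_two_fold_manual_trace(self):
        """Per-fold metrics match hand-executed train/test bookkeeping."""
        X, y = _toy_separable(n=24, gap=2.0, seed=9)
        idx = np.arange(24)
        fold_a, fold_b = idx[::2], idx[1::2]  # interleaved, both classes each
        plan = ow.SplitPlan(
            optimization_idx=np.array([], int),
            crossval_idx=idx,
            folds=[(fold_b, fold_a), (fold_a, fold_b)],
        )
        model = make_classifier(ModelSpec("lr"))
        rep = ow.kfold_evaluate(plan, model, X, y)
        for (tr, te), got in zip(plan.folds, rep.per_fold):
            m = make_classifier(ModelSpec("lr")).fit(X[tr], y[tr])
            expect = ow.diagnostic_metrics(m.predict(X[te]), y[te])
            assert got == expect

    def test_single_class_fold_rejected(self):
        X = np.random.default_rng(0).normal(size=(8, 2))
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        plan = ow.SplitPlan(
            optimization_idx=np.array([], int),
            crossval_idx=np.arange(8),
            folds=[(np.arange(4), np.arange(4, 8))],
        )
        with pytest.raises(ValueError, match="single class"):
            ow.kfold_evaluate(plan, make_classifier(ModelSpec("lr")), X, y)


class TestLeakage:
    def test_corrupting_heldout_labels_leaves_model_identical(self):
        X, y = _toy_separable(n=60, gap=1.5, seed=12)
        plan = ow.make_split(y, seed=2)
        model = make_classifier(ModelSpec("lr"))
        rep = ow.kfold_evaluate(plan, model, X, y, return_models=True)
        y_bad = y.copy()
        _, te0 = plan.folds[0]
        y_bad[te0] = 1 - y_bad[te0]
        rep_bad = ow.kfold_evaluate(plan, model, X, y_bad, return_models=True)
        a = rep.models[0]["model"]
        b = rep_bad.models[0]["model"]
        np.testing.assert_array_equal(a.coef_, b.coef_)
        np.testing.assert_array_equal(a.intercept_, b.intercept_)


class TestMannWhitney:
    def test_identical_groups_no_shift(self):
        a = np.arange(10.0)
        _, p = ow.mannwhitney_compare(a, a.copy())
        assert p > 0.9

    def test_complete_separation(self):
        u, _ = ow.mannwhitney_compare([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert u == 0.0

    def test_exact_enumeration_oracle(self):
        rng = np.random.default_rng(14)
        a = rng.normal(size=3)
        b = rng.normal(size=3) + 0.5
        u_obs, p = ow.mannwhitney_compare(a, b)
        # enumerate all assignments of the 6 ranks to group A
        pooled = np.concatenate([a, b])
        ranks = rankdata(pooled)
        n = len(pooled)
        u_all = []
        for comb in combinations(range(n), 3):
            r = ranks[list(comb)].sum()
            u_all.append(r - 3 * 4 / 2)
        u_all = np.array(u_all)
        u_a = ranks[:3].sum() - 6.0
        # two-sided exact p: tail probability of |U - mean| as extreme
        mean_u = 4.5
        p_exact = np.mean(np.abs(u_all - mean_u) >= abs(u_a - mean_u) - 1e-12)
        assert p == pytest.approx(p_exact, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ow.mannwhitney_compare([], [1.0])
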