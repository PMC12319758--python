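"""Class-weighted elastic-net logistic regression with nested LOOCV.

The model minimizes the penalized weighted binomial deviance

    (1/N) sum_i w_i [ log(1 + exp(eta_i)) - y_i eta_i ]
        + lambda ( alpha ||beta||_1 + (1 - alpha)/2 ||beta||_2^2 ),

eta_i = beta0 + x_i beta, with the intercept unpenalized.  Class weights are
w_c = N / (2 n_c) ("inversely proportional to the outcome frequencies",
normalized to total weight N), so the minority class counts more.  The
solver is coordinate descent on the iteratively reweighted least-squares
quadratic approximation with soft-thresholding, warm-started along a
log-spaced lambda path; a backtracking step guarantees the true objective
never increases between outer iterations.

Evaluation follows the nested leave-one-out protocol: the outer loop holds
out one subject at a time; inside each outer training set, class weights are
recomputed and lambda is chosen by stratified inner cross-validation
minimizing mean held-out weighted binomial deviance (ties go to the larger,
sparser lambda).  Pooled held-out probabilities give AUC / accuracy /
sensitivity / specificity, with bootstrap percentile confidence intervals
for the AUC, and a final all-data fit at the median selected lambda yields
|coefficient| feature importances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.stats import rankdata

__all__ = [
    "ENConfig",
    "ElasticNetFit",
    "FoldResult",
    "ClassifierReport",
    "class_weights",
    "lambda_path",
    "fit_en_logistic",
    "inner_cv_lambda",
    "nested_loocv",
    "performance_metrics",
    "bootstrap_auc_ci",
    "final_importance",
    "classify_table",
]


@dataclass(frozen=True)
class ENConfig:
    """Elastic-net and cross-validation settings."""

    alpha: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    inner_folds: int = 10
    tol: float = 1e-7
    max_iter: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.alpha <= 1):
            raise ValueError("alpha must lie in [0, 1]")
        if self.inner_folds < 2:
            raise ValueError("need at least 2 inner folds")


@dataclass
class ElasticNetFit:
    intercept: float
    coef: np.ndarray
    lam: float
    alpha: float
    objective: float
    n_iter: int
    objective_path: np.ndarray  # per-outer-iteration true objective

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        eta = self.intercept + X @ self.coef
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class FoldResult:
    subject: str
    probability: float
    label: int
    lam: float


@dataclass
class ClassifierReport:
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    auc_ci: tuple
    folds: list
    importances: pd.Series  # nonzero |coef| descending
    coefficients: pd.Series
    lambda_final: float


def class_weights(labels: np.ndarray) -> np.ndarray:
    """Per-observation weights w_c = N / (2 n_c); both classes must appear."""
    y = np.asarray(labels)
    n = y.size
    n_pos = int(np.sum(y == 1))
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    w_pos, w_neg = n / (2.0 * n_pos), n / (2.0 * n_neg)
    return np.where(y == 1, w_pos, w_neg).astype(float)


def lambda_path(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    alpha: float,
    n_lambda: int = 100,
    min_ratio: float = 1e-4,
) -> np.ndarray:
    """Log-spaced decreasing lambda grid from lambda_max down.

    lambda_max = max_j |sum_i w_i x_ij (y_i - ybar_w)| / (N alpha) is the
    smallest lambda at which the all-zero coefficient vector is optimal
    (KKT).  Requires alpha > 0 for a finite lambda_max.
    """
    if alpha <= 0:
        raise ValueError("lambda_max is infinite at alpha = 0")
    X = np.asarray(X, dtype=float)
    if np.all(X.std(axis=0) == 0):
        raise ValueError("all features are constant")
    N = y.size
    ybar = np.average(y, weights=weights)
    grad = X.T @ (weights * (y - ybar)) / (N * alpha)
    lam_max = float(np.max(np.abs(grad)))
    if lam_max <= 0:
        lam_max = 1e-3
    if n_lambda == 1:
        return np.array([lam_max])
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


@njit(cache=True)
def _objective(X, y, w, b0, beta, lam, alpha):
    N = X.shape[0]
    loss = 0.0
    for i in range(N):
        eta = b0
        for j in range(X.shape[1]):
            eta += X[i, j] * beta[j]
        if eta > 30.0:
            ll = eta
        else:
            ll = np.log1p(np.exp(eta))
        loss += w[i] * (ll - y[i] * eta)
    l1 = 0.0
    l2 = 0.0
    for j in range(beta.size):
        l1 += abs(beta[j])
        l2 += beta[j] * beta[j]
    return loss / N + lam * (alpha * l1 + 0.5 * (1.0 - alpha) * l2)


@njit(cache=True)
def _cd_sweep(X, r, beta, om, om_sum, xsq, lam, alpha, idx, b0):
    """One coordinate-descent sweep over the coordinates in ``idx`` plus the
    intercept, updating ``r`` and ``beta`` in place.  Returns (max step, b0)."""
    N = X.shape[0]
    delta = 0.0
    num = 0.0
    for i in range(N):
        num += om[i] * (r[i] + b0)
    b0_new = num / om_sum
    d0 = b0_new - b0
    if abs(d0) > delta:
        delta = abs(d0)
    for i in range(N):
        r[i] -= d0
    b0 = b0_new
    for jj in range(idx.size):
        j = idx[jj]
        bj = beta[j]
        rho = 0.0
        for i in range(N):
            rho += om[i] * X[i, j] * (r[i] + X[i, j] * bj)
        thr = lam * alpha
        if rho > thr:
            bj_new = (rho - thr) / (xsq[j] + lam * (1.0 - alpha))
        elif rho < -thr:
            bj_new = (rho + thr) / (xsq[j] + lam * (1.0 - alpha))
        else:
            bj_new = 0.0
        d = bj_new - bj
        if d != 0.0:
            for i in range(N):
                r[i] -= X[i, j] * d
            beta[j] = bj_new
            if abs(d) > delta:
                delta = abs(d)
    return delta, b0


@njit(cache=True)
def _fit_single(X, y, w, alpha, lam, beta0, b0_init, tol, max_iter):
    """IRLS + coordinate descent for one lambda.

    Returns (b0, beta, objective, n_iter, objective_path).  A halving
    backtracking step keeps the true objective non-increasing.
    """
    N, p = X.shape
    beta = beta0.copy()
    b0 = b0_init
    obj = _objective(X, y, w, b0, beta, lam, alpha)
    obj_path = np.empty(max_iter + 1)
    obj_path[0] = obj
    n_done = 0
    for it in range(max_iter):
        beta_old = beta.copy()
        b0_old = b0
        # IRLS working response and weights
        eta = np.empty(N)
        for i in range(N):
            e = b0
            for j in range(p):
                e += X[i, j] * beta[j]
            eta[i] = e
        mu = 1.0 / (1.0 + np.exp(-eta))
        v = mu * (1.0 - mu)
        for i in range(N):
            if v[i] < 1e-5:
                v[i] = 1e-5
        z = eta + (y - mu) / v
        om = w * v / N  # working observation weights
        om_sum = om.sum()
        # cache column quantities
        xsq = np.empty(p)
        for j in range(p):
            s = 0.0
            for i in range(N):
                s += om[i] * X[i, j] * X[i, j]
            xsq[j] = s
        # residual r = z - b0 - X beta
        r = z - eta
        # coordinate descent on the quadratic: alternate one full sweep with
        # sweeps restricted to the active (nonzero) set, glmnet style.  The
        # quadratic subproblems are solved to the same tolerance as the
        # outer loop; active-set sweeps do the bulk of the work
        for full_pass in range(15):
            delta = _cd_sweep(X, r, beta, om, om_sum, xsq, lam, alpha,
                              np.arange(p), b0)
            b0 = delta[1]
            if delta[0] < tol:
                break
            active = np.nonzero(beta)[0]
            for _ in range(100):
                da = _cd_sweep(X, r, beta, om, om_sum, xsq, lam, alpha,
                               active, b0)
                b0 = da[1]
                if da[0] < tol:
                    break
        # backtrack toward the previous iterate if the true objective rose
        obj_new = _objective(X, y, w, b0, beta, lam, alpha)
        halvings = 0
        while obj_new > obj + 1e-12 and halvings < 30:
            b0 = 0.5 * (b0 + b0_old)
            for j in range(p):
                beta[j] = 0.5 * (beta[j] + beta_old[j])
            obj_new = _objective(X, y, w, b0, beta, lam, alpha)
            halvings += 1
        improvement = obj - obj_new
        obj = obj_new
        obj_path[it + 1] = obj
        n_done = it + 1
        # outer convergence: max coefficient change below tol, or the
        # objective has stopped improving (plateau under near-separation)
        move = abs(b0 - b0_old)
        for j in range(p):
            if abs(beta[j] - beta_old[j]) > move:
                move = abs(beta[j] - beta_old[j])
        if move < tol * 10.0:
            break
        if it > 2 and improvement < 1e-10 * (1.0 + abs(obj)):
            break
    # zero out sub-precision coefficients: soft-threshold boundary overshoot
    # by ~1 ULP at lambda_max must not masquerade as an active feature
    scale = 1.0
    for j in range(p):
        if abs(beta[j]) > scale:
            scale = abs(beta[j])
    for j in range(p):
        if abs(beta[j]) < 1e-12 * scale:
            beta[j] = 0.0
    return b0, beta, obj, n_done, obj_path[: n_done + 1]


def fit_en_logistic(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    alpha: float,
    lam: float,
    config: ENConfig = ENConfig(),
    warm: tuple | None = None,
) -> ElasticNetFit:
    """Fit one penalized weighted logistic regression."""
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(np.isnan(X)):
        raise ValueError("X contains missing values; impute upstream")
    w = np.asarray(weights, dtype=float)
    if warm is None:
        ybar = np.average(y, weights=w)
        b0_init = float(np.log(ybar / (1 - ybar)))
        beta_init = np.zeros(X.shape[1])
    else:
        b0_init, beta_init = warm
        beta_init = np.asarray(beta_init, dtype=float).copy()
    b0, beta, obj, n_iter, path = _fit_single(
        X, y, w, float(alpha), float(lam), beta_init, float(b0_init),
        config.tol, config.max_iter,
    )
    if n_iter >= config.max_iter:
        move = float(np.max(np.abs(np.diff(path[-2:])))) if path.size > 1 else np.nan
        raise RuntimeError(
            f"elastic-net fit did not converge in {config.max_iter} iterations "
            f"(lambda={lam:.3g}, last objective change {move:.3g})"
        )
    return ElasticNetFit(
        intercept=float(b0), coef=np.asarray(beta), lam=float(lam),
        alpha=float(alpha), objective=float(obj), n_iter=int(n_iter),
        objective_path=np.asarray(path),
    )


def _fit_path(X, y, w, alpha, lambdas, config) -> list[ElasticNetFit]:
    fits = []
    warm = None
    for lam in lambdas:
        fit = fit_en_logistic(X, y, w, alpha, lam, config, warm=warm)
        warm = (fit.intercept, fit.coef)
        fits.append(fit)
    return fits


def _binomial_deviance(y, p, w) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    dev = -2.0 * (y * np.log(p) + (1 - y) * np.log(1 - p))
    return float(np.average(dev, weights=w))


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator):
    """Deterministic stratified fold assignment; every fold keeps both
    classes where counts permit."""
    n = y.size
    fold = np.empty(n, dtype=int)
    for cls in (0, 1):
        idx = np.nonzero(y == cls)[0]
        idx = idx[rng.permutation(idx.size)]
        fold[idx] = np.arange(idx.size) % k
    return fold


def inner_cv_lambda(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    alpha: float,
    lambdas: np.ndarray,
    config: ENConfig,
    rng: np.random.Generator | None = None,
    fold: np.ndarray | None = None,
) -> float:
    """Lambda minimizing mean held-out weighted binomial deviance.

    Folds are stratified by class (or supplied via ``fold``, the common-fold
    convention that keeps selection stable across outer LOOCV folds); ties
    pick the larger (sparser) lambda.
    """
    k = min(config.inner_folds, int(np.sum(y == 1)), int(np.sum(y == 0)))
    if k < 2:
        raise ValueError("cannot stratify: a class has fewer than 2 members")
    if fold is None:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        fold = _stratified_folds(y, k, rng)
    else:
        fold = np.asarray(fold) % k
    dev = np.zeros((k, lambdas.size))
    for f in range(k):
        tr, va = fold != f, fold == f
        if len(np.unique(y[va])) < 1 or len(np.unique(y[tr])) < 2:
            raise ValueError("degenerate inner fold")
        fits = _fit_path(X[tr], y[tr], weights[tr], alpha, lambdas, config)
        for li, fit in enumerate(fits):
            p = fit.predict_proba(X[va])
            dev[f, li] = _binomial_deviance(y[va], p, weights[va])
    mean_dev = dev.mean(axis=0)
    # lambdas are decreasing, argmin returns the first minimum = largest lambda
    return float(lambdas[int(np.argmin(mean_dev))])


def nested_loocv(
    X: np.ndarray,
    y: np.ndarray,
    subjects: list[str] | None = None,
    config: ENConfig = ENConfig(),
) -> list[FoldResult]:
    """Leave-one-out outer loop with inner-CV lambda selection.

    Class weights and the lambda grid are recomputed inside every outer fold
    from the training subjects only, so nothing about the held-out subject
    leaks into model selection.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = y.size
    if n < 10:
        raise ValueError("nested LOOCV needs at least 10 subjects")
    if np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
        raise ValueError("need at least 2 subjects per class")
    if subjects is None:
        subjects = [f"s{i:03d}" for i in range(n)]
    rng = np.random.default_rng(config.seed)
    results: list[FoldResult] = []
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        Xtr, ytr = X[tr], y[tr]
        try:
            w = class_weights(ytr)
            lambdas = lambda_path(
                Xtr, ytr, w, config.alpha, config.n_lambda, config.lambda_min_ratio
            )
            # inner folds are re-randomized for every outer fold, as a fresh
            # cross-validation call inside each training set would do
            lam = inner_cv_lambda(
                Xtr, ytr, w, config.alpha, lambdas, config, rng=rng
            )
            # refit on the full training set along the path down to lam
            fits = _fit_path(
                Xtr, ytr, w, config.alpha, lambdas[lambdas >= lam], config
            )
            fit = fits[-1]
        except Exception as exc:  # annotate with the fold
            raise RuntimeError(f"outer fold {i} ({subjects[i]}): {exc}") from exc
        # round to 12 decimals: differences at floating-point precision are
        # ties, not rankable signal (an all-null model must give AUC 0.5)
        p = float(np.round(fit.predict_proba(X[i : i + 1])[0], 12))
        results.append(FoldResult(subject=subjects[i], probability=p,
                                  label=int(y[i]), lam=lam))
    return results


def auc_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank (Mann-Whitney) AUC with half credit for ties."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y == 1))
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def performance_metrics(
    folds: list[FoldResult],
    threshold: float = 0.5,
    paper_convention: bool = False,
) -> dict:
    """AUC plus thresholded accuracy / sensitivity / specificity.

    TBI (label 1) is the positive class.  By default sensitivity and
    specificity use the conventional per-class denominators; the
    ``paper_convention`` flag divides both by the total subject count
    instead.
    """
    y = np.array([f.label for f in folds])
    p = np.array([f.probability for f in folds])
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    n_pos, n_neg, n = int(np.sum(y == 1)), int(np.sum(y == 0)), y.size
    denom_pos, denom_neg = (n, n) if paper_convention else (n_pos, n_neg)
    return {
        "auc": auc_score(y, p),
        "accuracy": (tp + tn) / n,
        "sensitivity": tp / denom_pos,
        "specificity": tn / denom_neg,
    }


def bootstrap_auc_ci(
    folds: list[FoldResult],
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap 95% CI for the pooled AUC.

    Subjects are resampled with replacement keeping N; single-class
    replicates are skipped (more than half degenerate is an error).
    """
    y = np.array([f.label for f in folds])
    p = np.array([f.probability for f in folds])
    if np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
        raise ValueError("need at least 2 subjects per class")
    rng = np.random.default_rng(seed)
    aucs = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, y.size, y.size)
        yb = y[idx]
        if yb.min() == yb.max():
            skipped += 1
            continue
        aucs.append(auc_score(yb, p[idx]))
    if skipped > n_boot / 2:
        raise ValueError(f"{skipped}/{n_boot} bootstrap replicates degenerate")
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def final_importance(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    folds: list[FoldResult],
    config: ENConfig = ENConfig(),
) -> tuple[pd.Series, pd.Series, float]:
    """All-data fit at the median LOOCV lambda; importance = |coefficient|.

    Returns (importances descending, nonzero coefficients, lambda used).
    Warns and returns empty series when the final model is all zeros.
    """
    import warnings

    lam_med = float(np.median([f.lam for f in folds]))
    w = class_weights(np.asarray(y))
    lambdas = lambda_path(X, y, w, config.alpha, config.n_lambda,
                          config.lambda_min_ratio)
    if lam_med >= lambdas[0]:
        warnings.warn("median lambda at or above lambda_max: empty final model",
                      stacklevel=2)
        empty = pd.Series(dtype=float)
        return empty, empty, lam_med
    path = np.append(lambdas[lambdas > lam_med], lam_med)
    fit = _fit_path(np.asarray(X, float), np.asarray(y, float), w,
                    config.alpha, path, config)[-1]
    coef = pd.Series(fit.coef, index=feature_names)
    nz = coef[coef != 0.0]
    if nz.empty:
        warnings.warn("final elastic-net model has no nonzero coefficients",
                      stacklevel=2)
    imp = nz.abs().sort_values(ascending=False)
    return imp, nz, lam_med


def classify_table(
    table: pd.DataFrame,
    metric: str = "all",
    config: ENConfig = ENConfig(),
    n_boot: int = 1000,
    paper_convention: bool = False,
) -> ClassifierReport:
    """Run the full nested-LOOCV analysis on a standardized feature table.

    ``metric`` selects one DTI metric's columns ('FA', 'MD', 'RD', 'AD') or
    'all' for the joint feature set.  Labels: TBI = 1, sham = 0.
    """
    from .features import split_covariates

    _, feats = split_covariates(table)
    if metric.lower() != "all":
        feats = [c for c in feats if c.endswith(f"__{metric.upper()}")]
        if not feats:
            raise ValueError(f"no feature columns for metric {metric!r}")
    X = table[feats].to_numpy(dtype=float)
    y = (table["group"] == "TBI").to_numpy(dtype=int)
    subjects = table["subject"].astype(str).tolist()
    folds = nested_loocv(X, y, subjects, config)
    perf = performance_metrics(folds, paper_convention=paper_convention)
    ci = bootstrap_auc_ci(folds, n_boot=n_boot, seed=config.seed)
    imp, coefs, lam = final_importance(X, y, feats, folds, config)
    return ClassifierReport(
        auc=perf["auc"], accuracy=perf["accuracy"],
        sensitivity=perf["sensitivity"], specificity=perf["specificity"],
        auc_ci=ci, folds=folds, importances=imp, coefficients=coefs,
        lambda_final=lam,
    )
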