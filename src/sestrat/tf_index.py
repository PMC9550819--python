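"""Core-TF selection and the multi-TF stratification index.

For each cluster a one-vs-rest L1-penalized (LASSO) logistic regression is
fit on standardized log2 TF expression, with the penalty chosen by
stratified cross-validation under the 1-SE rule. The cluster's core TF is
the nonzero-weight TF with the largest absolute standardized weight. The
scalar index is the intercept-free linear predictor of one designated
cluster's model (by default the worst-prognosis cluster), so higher values
mean "more like that cluster"; cluster prediction takes the argmax linear
predictor across the per-cluster models.

The LASSO solver is cyclic coordinate descent on the iteratively reweighted
quadratic approximation of the logistic deviance (intercept unpenalized),
run until the maximum coefficient change falls below 1e-7 and the KKT
stationarity conditions hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .io_formats import ExprMatrix, logger

_TOL = 1e-7
_MAX_OUTER = 200
_MIN_WEIGHT = 1e-5  # lower bound on IRLS observation weights


def _objective(X: np.ndarray, y: np.ndarray, w: np.ndarray, b: float, lam: float) -> float:
    eta = b + X @ w
    # log(1+e^eta) - y*eta, computed stably
    nll = np.logaddexp(0.0, eta) - y * eta
    return float(nll.mean() + lam * np.abs(w).sum())


def _soft(x: float, t: float) -> float:
    return np.sign(x) * max(abs(x) - t, 0.0)


def lasso_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    w0: np.ndarray | None = None,
    b0: float | None = None,
    return_trace: bool = False,
):
    """L1-penalized logistic regression by coordinate descent.

    Minimizes (1/n) * logistic deviance + lam * sum|w| with an unpenalized
    intercept. Warm starts via ``w0``/``b0``. Returns (weights, intercept),
    or (weights, intercept, objective_trace) when ``return_trace``; the
    trace is the penalized objective after each outer reweighting step and
    is non-increasing by construction (step-halving safeguard).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in X")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("y contains a single class")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    n, p = X.shape
    w = np.zeros(p) if w0 is None else w0.astype(float).copy()
    ybar = y.mean()
    b = float(np.log(ybar / (1 - ybar))) if b0 is None else float(b0)

    obj = _objective(X, y, w, b, lam)
    trace = [obj]
    for _ in range(_MAX_OUTER):
        eta = b + X @ w
        prob = 1.0 / (1.0 + np.exp(-eta))
        v = np.clip(prob * (1.0 - prob), _MIN_WEIGHT, None)
        z = eta + (y - prob) / v
        w_new, b_new = _cd_quadratic(X, z, v, lam, w.copy(), b)
        # step-halving safeguard keeps the penalized deviance non-increasing
        new_obj = _objective(X, y, w_new, b_new, lam)
        step = 1.0
        while new_obj > obj + 1e-12 and step > 1e-4:
            step /= 2.0
            w_new = w + step * (w_new - w)
            b_new = b + step * (b_new - b)
            new_obj = _objective(X, y, w_new, b_new, lam)
        delta = max(float(np.max(np.abs(w_new - w))) if len(w) else 0.0, abs(b_new - b))
        w, b, obj = w_new, float(b_new), new_obj
        trace.append(obj)
        if delta < _TOL and _kkt_violation(X, y, w, b, lam) < 1e-7:
            break
    # snap numerical dust to exact zero (e.g. ties between duplicated
    # features leave ~1e-10 remainders that are zero in exact arithmetic)
    w[np.abs(w) < 1e-8] = 0.0
    if return_trace:
        return w, b, trace
    return w, b


def _cd_quadratic(
    X: np.ndarray, z: np.ndarray, v: np.ndarray, lam: float, w: np.ndarray, b: float
) -> tuple[np.ndarray, float]:
    """Inner cyclic coordinate descent on the weighted least-squares surrogate."""
    n, p = X.shape
    vsum = v.sum()
    denom = (v[:, None] * X * X).sum(axis=0) / n
    r = z - b - X @ w  # working residual
    for _ in range(1000):
        max_delta = 0.0
        b_new = b + (v * r).sum() / vsum
        r -= b_new - b
        max_delta = max(max_delta, abs(b_new - b))
        b = b_new
        for j in range(p):
            if denom[j] == 0:
                continue
            rho = (v * X[:, j] * (r + X[:, j] * w[j])).sum() / n
            wj = _soft(rho, lam) / denom[j]
            if wj != w[j]:
                r -= X[:, j] * (wj - w[j])
                max_delta = max(max_delta, abs(wj - w[j]))
                w[j] = wj
        if max_delta < _TOL * 0.1:
            break
    return w, b


def _kkt_violation(X, y, w, b, lam) -> float:
    """Maximum KKT stationarity violation of the true penalized objective."""
    n = len(y)
    prob = 1.0 / (1.0 + np.exp(-(b + X @ w)))
    g = X.T @ (prob - y) / n
    viol = abs(prob.mean() - y.mean())  # intercept stationarity
    for j in range(len(w)):
        if w[j] == 0.0:
            viol = max(viol, abs(g[j]) - lam)
        else:
            viol = max(viol, abs(g[j] + lam * np.sign(w[j])))
    return float(viol)


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which the all-zero solution satisfies the KKT
    conditions: max_j |X_j^T (y - ybar)| / n."""
    y = np.asarray(y, dtype=float)
    return float(np.max(np.abs(X.T @ (y - y.mean()))) / len(y))


def _binomial_deviance(X, y, w, b) -> float:
    eta = b + X @ w
    return float(2.0 * (np.logaddexp(0.0, eta) - y * eta).mean())


def _make_folds(n, y, n_folds, seed):
    for attempt in range(10):
        rs = seed + attempt
        try:
            splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rs)
            folds = list(splitter.split(np.zeros(n), y))
        except ValueError:
            splitter = KFold(n_splits=n_folds, shuffle=True, random_state=rs)
            folds = list(splitter.split(np.zeros(n)))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
            return folds
    raise ValueError("could not build folds with both classes in every training set")


def cv_select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 50,
    lambda_min_ratio: float = 0.001,
) -> float:
    """1-SE-rule penalty from stratified cross-validation.

    The grid is ``n_lambdas`` log-spaced values from lambda_max down to
    ``lambda_min_ratio`` * lambda_max; the chosen lambda is the largest one
    whose mean CV deviance is within one standard error of the minimum.
    """
    if n_folds < 3:
        raise ValueError("n_folds must be >= 3")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    lmax = lambda_max(X, y)
    grid = np.geomspace(lmax, lambda_min_ratio * lmax, n_lambdas)
    folds = _make_folds(len(y), y, n_folds, seed)
    dev = np.zeros((len(folds), len(grid)))
    for f, (tr, va) in enumerate(folds):
        w, b = None, None
        for li, lam in enumerate(grid):
            w, b = lasso_logistic(X[tr], y[tr], lam, w0=w, b0=b)
            dev[f, li] = _binomial_deviance(X[va], y[va], w, b)
    mean = dev.mean(axis=0)
    se = dev.std(axis=0, ddof=1) / np.sqrt(len(folds))
    best = int(np.argmin(mean))
    within = np.flatnonzero(mean <= mean[best] + se[best])
    return float(grid[within[0]])  # grid is descending, so first = largest lambda


@dataclass
class TfIndexModel:
    """Per-cluster LASSO models over a candidate TF panel."""

    candidate_tfs: list[str]
    weights: dict[int, np.ndarray]      # cluster -> standardized weights
    intercepts: dict[int, float]
    means: np.ndarray                   # per-TF mean of log2 expression
    sds: np.ndarray                     # per-TF sd (> 0)
    lambdas: dict[int, float]
    core_tfs: dict[int, str | None]
    index_cluster: int

    @property
    def selected_tfs(self) -> list[str]:
        sel: set[str] = set()
        for w in self.weights.values():
            sel.update(np.array(self.candidate_tfs)[w != 0])
        return sorted(sel)


def _standardized(expr: ExprMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    log = expr.to_log2().values  # TFs x samples
    means = log.mean(axis=1)
    sds = log.std(axis=1, ddof=0)
    if (sds == 0).any():
        bad = [t for t, s in zip(expr.feature_ids, sds) if s == 0]
        raise ValueError(f"zero-variance candidate TFs: {bad[:5]}")
    Z = ((log - means[:, None]) / sds[:, None]).T  # samples x TFs
    return Z, means, sds


def fit_core_tfs(
    expr: ExprMatrix,
    labels: Sequence[int],
    n_folds: int = 10,
    seed: int = 0,
    index_cluster: int | None = None,
) -> TfIndexModel:
    """One-vs-rest LASSO per cluster; the core TF is the top-|weight| TF.

    ``expr`` must be restricted to the candidate TF panel. ``index_cluster``
    designates whose linear predictor defines the scalar index; the caller
    should pass the worst-prognosis cluster (defaults to the highest cluster
    number when not given).
    """
    labels = np.asarray(labels)
    clusters = sorted(int(c) for c in np.unique(labels))
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters to fit one-vs-rest models")
    Z, means, sds = _standardized(expr)
    weights, intercepts, lambdas, core = {}, {}, {}, {}
    for c in clusters:
        y = (labels == c).astype(float)
        lam = cv_select_lambda(Z, y, n_folds=n_folds, seed=seed + c)
        w, b = lasso_logistic(Z, y, lam)
        weights[c], intercepts[c], lambdas[c] = w, b, lam
        nz = np.flatnonzero(w)
        if len(nz) == 0:
            logger.warning("cluster %d: all LASSO weights zero; no core TF", c)
            core[c] = None
        else:
            core[c] = expr.feature_ids[nz[np.argmax(np.abs(w[nz]))]]
    if index_cluster is None:
        index_cluster = clusters[-1]
    if index_cluster not in clusters:
        raise ValueError(f"index_cluster {index_cluster} not among labels")
    return TfIndexModel(
        candidate_tfs=list(expr.feature_ids),
        weights=weights,
        intercepts=intercepts,
        means=means,
        sds=sds,
        lambdas=lambdas,
        core_tfs=core,
        index_cluster=index_cluster,
    )


def _standardize_for(model: TfIndexModel, expr: ExprMatrix) -> np.ndarray:
    missing = [t for t in model.selected_tfs if t not in expr.feature_ids]
    if missing:
        raise ValueError(f"expression matrix missing selected TFs: {missing}")
    present = [t for t in model.candidate_tfs if t in expr.feature_ids]
    sub = expr.subset_features(present).to_log2().values  # present x samples
    Z = np.zeros((len(expr.sample_ids), len(model.candidate_tfs)))
    pos = {t: i for i, t in enumerate(model.candidate_tfs)}
    for row, t in enumerate(present):
        i = pos[t]
        Z[:, i] = (sub[row] - model.means[i]) / model.sds[i]
    return Z


def build_tf_index(model: TfIndexModel, expr: ExprMatrix) -> np.ndarray:
    """Per-sample scalar index: the index cluster's intercept-free linear
    predictor on standardized log2 expression (higher = more index-like)."""
    Z = _standardize_for(model, expr)
    return Z @ model.weights[model.index_cluster]


def predict_clusters(model: TfIndexModel, expr: ExprMatrix) -> np.ndarray:
    """Argmax over per-cluster linear predictors; ties go to the lower cluster."""
    Z = _standardize_for(model, expr)
    clusters = sorted(model.weights)
    scores = np.column_stack(
        [model.intercepts[c] + Z @ model.weights[c] for c in clusters]
    )
    return np.array(clusters)[np.argmax(scores, axis=1)]
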