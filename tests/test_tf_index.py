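import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from sestrat import (
    ExprMatrix,
    build_tf_index,
    cv_select_lambda,
    fit_core_tfs,
    lambda_max,
    lasso_logistic,
    predict_clusters,
)
from sestrat.tf_index import TfIndexModel, _kkt_violation, _objective

TF_PANEL = [f"TF{i + 1:02d}" for i in range(20)]


def toy_problem(n=40, p=5, informative=0, effect=2.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    X = (X - X.mean(0)) / X.std(0)
    y = np.zeros(n)
    y[: n // 2] = 1
    X[y == 1, informative] += effect
    X = (X - X.mean(0)) / X.std(0)
    return X, y


def test_all_zero_at_lambda_max():
    X, y = toy_problem()
    lmax = lambda_max(X, y)
    w, b = lasso_logistic(X, y, lmax * 1.0001)
    assert np.all(w == 0.0)
    w2, _ = lasso_logistic(X, y, lmax * 0.5)
    assert np.any(w2 != 0.0)


def test_exactly_uncorrelated_feature_stays_zero():
    """A feature orthogonal to every function of (x1, y) keeps weight 0.

    Built by duplicating (x1, y) rows and giving the extra feature opposite
    signs within each duplicate pair: its gradient is identically zero.
    """
    rng = np.random.default_rng(2)
    x1 = np.repeat(rng.normal(size=10), 2)
    y = np.repeat((rng.random(10) < 0.5).astype(float), 2)
    if len(np.unique(y)) < 2:
        y[:2] = [0.0, 0.0]
        y[-2:] = [1.0, 1.0]
    x2 = np.tile([1.0, -1.0], 10)
    X = np.column_stack([x1, x2])
    w, b = lasso_logistic(X, y, 0.01)
    assert w[1] == 0.0


def test_single_feature_matches_grid_oracle():
    """1-D coordinate-descent solution equals brute-force grid minimization."""
    rng = np.random.default_rng(7)
    x = rng.normal(size=20)
    x = (x - x.mean()) / x.std()
    y = (rng.random(20) < 1 / (1 + np.exp(-1.5 * x))).astype(float)
    lam = 0.05
    X = x[:, None]

    def profiled(wv):
        res = minimize_scalar(
            lambda b: _objective(X, y, np.array([wv]), b, lam), bounds=(-5, 5),
            method="bounded", options={"xatol": 1e-10},
        )
        return res.fun

    grid = np.linspace(-3, 3, 6001)
    vals = [profiled(wv) for wv in grid]
    w_grid = grid[int(np.argmin(vals))]
    # refine around the best grid point
    fine = np.linspace(w_grid - 2e-3, w_grid + 2e-3, 801)
    w_grid = fine[int(np.argmin([profiled(wv) for wv in fine]))]
    w, b = lasso_logistic(X, y, lam)
    assert w[0] == pytest.approx(w_grid, abs=1e-4)


def test_kkt_satisfied_after_fits():
    for seed in range(5):
        X, y = toy_problem(seed=seed)
        for lam in (0.005, 0.02, 0.1):
            w, b = lasso_logistic(X, y, lam)
            assert _kkt_violation(X, y, w, b, lam) <= 1e-6


def test_objective_monotone_nonincreasing():
    X, y = toy_problem(n=60, p=8, seed=3)
    _, _, trace = lasso_logistic(X, y, 0.02, return_trace=True)
    diffs = np.diff(trace)
    assert (diffs <= 1e-12).all()


def test_lasso_input_validation():
    X, y = toy_problem()
    with pytest.raises(ValueError):
        lasso_logistic(X, np.zeros(len(y)), 0.1)  # one class
    with pytest.raises(ValueError):
        lasso_logistic(X * np.nan, y, 0.1)
    with pytest.raises(ValueError):
        lasso_logistic(X, y, -0.1)


def test_cross_check_against_sklearn():
    """Same objective as sklearn liblinear at C = 1/(n*lambda)."""
    from sklearn.linear_model import LogisticRegression

    X, y = toy_problem(n=80, p=6, effect=1.0, seed=4)
    lam = 0.02
    w, b = lasso_logistic(X, y, lam)
    sk = LogisticRegression(
        penalty="l1", C=1.0 / (len(y) * lam), solver="liblinear", tol=1e-10,
        max_iter=10_000,
    ).fit(X, y)
    ours = _objective(X, y, w, b, lam)
    theirs = _objective(X, y, sk.coef_[0], float(sk.intercept_[0]), lam)
    assert ours <= theirs + 1e-6
    np.testing.assert_allclose(w, sk.coef_[0], atol=2e-3)


def test_cv_retains_informative_feature():
    X, y = toy_problem(n=100, p=6, effect=3.0, seed=1)
    lam = cv_select_lambda(X, y, n_folds=5, seed=0)
    w, _ = lasso_logistic(X, y, lam)
    assert w[0] != 0.0


def test_cv_pure_noise_mostly_null():
    zeroed = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(60, 8))
        y = (rng.random(60) < 0.5).astype(float)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        lam = cv_select_lambda(X, y, n_folds=5, seed=seed)
        w, _ = lasso_logistic(X, y, lam)
        zeroed += np.all(w == 0.0)
    assert zeroed >= 9


def test_cv_leave_one_out_runs():
    X, y = toy_problem(n=12, p=2, effect=3.0, seed=0)
    lam = cv_select_lambda(X, y, n_folds=12, seed=0)
    assert lam > 0


def expr_from(values, features, samples):
    return ExprMatrix(pd.DataFrame(values, index=features, columns=samples))


def test_core_tf_recovery(cohort300, truth_labels300):
    model = fit_core_tfs(
        cohort300.mrna.subset_features(TF_PANEL), truth_labels300, seed=1
    )
    for c in (1, 2, 3):
        assert model.core_tfs[c] == cohort300.truth["driver_tfs"][str(c)][0]
    assert set(model.selected_tfs) >= {"TF01", "TF02", "TF03"}


def test_fit_core_tfs_requires_two_clusters(cohort300):
    with pytest.raises(ValueError):
        fit_core_tfs(
            cohort300.mrna.subset_features(TF_PANEL),
            np.ones(len(cohort300.mrna.sample_ids), dtype=int),
        )


def test_duplicated_driver_column_selects_exactly_one(cohort300, truth_labels300):
    sub = cohort300.mrna.subset_features(TF_PANEL)
    df = sub.df.copy()
    df.loc["TF01_dup"] = df.loc["TF01"].to_numpy()
    model = fit_core_tfs(ExprMatrix(df), truth_labels300, seed=1)
    w = model.weights[1]
    names = np.array(model.candidate_tfs)
    pair_nonzero = [n for n in ("TF01", "TF01_dup") if w[list(names).index(n)] != 0]
    assert len(pair_nonzero) == 1


def _manual_model(weights_by_cluster, tfs, means=None, sds=None, index_cluster=None):
    p = len(tfs)
    return TfIndexModel(
        candidate_tfs=list(tfs),
        weights={c: np.asarray(w, dtype=float) for c, w in weights_by_cluster.items()},
        intercepts={c: 0.0 for c in weights_by_cluster},
        means=np.zeros(p) if means is None else means,
        sds=np.ones(p) if sds is None else sds,
        lambdas={c: 0.1 for c in weights_by_cluster},
        core_tfs={c: None for c in weights_by_cluster},
        index_cluster=index_cluster or max(weights_by_cluster),
    )


def test_index_zero_weights_zero_index():
    model = _manual_model({1: [0.0], 2: [0.0]}, ["TF01"])
    m = expr_from([[1.0, 2.0, 4.0]], ["TF01"], ["a", "b", "c"])
    np.testing.assert_array_equal(build_tf_index(model, m), [0.0, 0.0, 0.0])


def test_index_single_tf_is_zscore():
    m = expr_from([[1.0, 3.0, 7.0]], ["TF01"], ["a", "b", "c"])
    log = m.to_log2().values[0]
    model = _manual_model(
        {1: [0.0], 2: [1.0]}, ["TF01"],
        means=np.array([log.mean()]), sds=np.array([log.std()]),
    )
    np.testing.assert_allclose(
        build_tf_index(model, m), (log - log.mean()) / log.std()
    )


def test_index_missing_selected_tf_named():
    model = _manual_model({1: [1.0]}, ["TF01"], index_cluster=1)
    m = expr_from([[1.0, 2.0]], ["OTHER"], ["a", "b"])
    with pytest.raises(ValueError, match="TF01"):
        build_tf_index(model, m)


def test_predict_tie_goes_to_lower_cluster():
    model = _manual_model({1: [1.0], 2: [1.0]}, ["TF01"], index_cluster=2)
    m = expr_from([[1.0, 2.0, 4.0]], ["TF01"], ["a", "b", "c"])
    np.testing.assert_array_equal(predict_clusters(model, m), [1, 1, 1])


def test_index_invariant_to_rescaling_nonselected(cohort300, truth_labels300):
    model = fit_core_tfs(
        cohort300.mrna.subset_features(TF_PANEL), truth_labels300, seed=1
    )
    unselected = [t for t in TF_PANEL if t not in model.selected_tfs]
    assert unselected, "need at least one non-selected TF for this test"
    df = cohort300.mrna.df.copy()
    df.loc[unselected[0]] *= 37.0
    np.testing.assert_allclose(
        build_tf_index(model, cohort300.mrna),
        build_tf_index(model, ExprMatrix(df)),
    )


def test_prediction_accuracy_and_index_auc(cohort300, truth_labels300):
    from sklearn.metrics import roc_auc_score

    model = fit_core_tfs(
        cohort300.mrna.subset_features(TF_PANEL), truth_labels300, seed=1,
        index_cluster=3,
    )
    idx = build_tf_index(model, cohort300.mrna)
    assert roc_auc_score(truth_labels300 == 3, idx) >= 0.95
    pred = predict_clusters(model, cohort300.mrna)
    assert (pred == truth_labels300).mean() >= 0.85


def test_prediction_permutation_equivariance(cohort300, truth_labels300):
    model = fit_core_tfs(
        cohort300.mrna.subset_features(TF_PANEL), truth_labels300, seed=1
    )
    rng = np.random.default_rng(0)
    perm = list(rng.permutation(cohort300.mrna.sample_ids))
    base = dict(zip(cohort300.mrna.sample_ids,
                    predict_clusters(model, cohort300.mrna)))
    permuted = predict_clusters(model, cohort300.mrna.align_samples(perm))
    assert [base[s] for s in perm] == list(permuted)
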