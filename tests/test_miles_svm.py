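"""1-norm SVM LP, prediction equivalence, λ tuning."""

import numpy as np
import pytest

from milespharm import (
    Bag,
    FeatureRegistry,
    Fingerprint,
    build_embedding,
    fit_l1svm,
    predict,
    prototypes,
    tune_lambda,
)
from milespharm.errors import ClassError
from milespharm.miles_svm import (
    DEFAULT_LAMBDA_GRID,
    L1SVMModel,
    decision_values,
    select_lambda,
    training_objective,
)

from conftest import random_dataset


def oracle_objective(X, y, lam):
    """Independent LP oracle: different variable layout, interior-point HiGHS.

    Variables [omega (free, n), b (free), xi (l)]; |omega| handled through
    t >= omega, t >= -omega auxiliary variables.
    """
    from scipy.optimize import linprog

    l, n = X.shape
    # z = [omega (n), t (n), b, xi (l)]
    c = np.concatenate([np.zeros(n), np.full(n, lam), [0.0], np.ones(l)])
    A = []
    b_ub = []
    for i in range(l):
        row = np.zeros(2 * n + 1 + l)
        row[:n] = -y[i] * X[i]
        row[2 * n] = -y[i]
        row[2 * n + 1 + i] = -1.0
        A.append(row)
        b_ub.append(-1.0)
    for r in range(n):  # omega_r - t_r <= 0 and -omega_r - t_r <= 0
        for sign in (1.0, -1.0):
            row = np.zeros(2 * n + 1 + l)
            row[r] = sign
            row[n + r] = -1.0
            A.append(row)
            b_ub.append(0.0)
    bounds = [(None, None)] * n + [(0, None)] * n + [(None, None)] + [(0, None)] * l
    res = linprog(c, A_ub=np.array(A), b_ub=np.array(b_ub), bounds=bounds,
                  method="highs-ipm")
    assert res.status == 0
    return res.fun


def test_huge_lambda_zeroes_all_weights(rng):
    X = rng.random((8, 5))
    y = np.array([1, 1, 1, 1, -1, -1, -1, -1], dtype=float)
    model = fit_l1svm(X, y, 1e6)
    assert np.all(model.omega == 0.0)
    assert model.gamma().size == 0


def test_hand_solved_single_feature_lp():
    X = np.array([[0.1], [0.9]])
    y = np.array([1.0, -1.0])
    model = fit_l1svm(X, y, 0.01)
    pred = np.where(X @ model.omega + model.bias >= 0, 1, -1)
    assert (pred == y).all()
    # separable at margin: omega = -2.5, b = 1.25 satisfies both constraints
    # with zero slack and is optimal at small lambda
    assert model.omega[0] == pytest.approx(-2.5, abs=1e-6)
    assert model.bias == pytest.approx(1.25, abs=1e-6)


def test_duplicated_column_preserves_objective_and_predictions(rng):
    X = rng.random((10, 1))
    y = np.where(X[:, 0] > 0.5, -1.0, 1.0)
    lam = 0.05
    single = fit_l1svm(X, y, lam)
    doubled = fit_l1svm(np.hstack([X, X]), y, lam)
    obj_single = training_objective(single, X, y)
    obj_doubled = training_objective(doubled, np.hstack([X, X]), y)
    assert obj_doubled == pytest.approx(obj_single, abs=1e-8)
    # total absolute weight matches the single-column magnitude
    assert np.abs(doubled.omega).sum() == pytest.approx(
        np.abs(single.omega).sum(), abs=1e-8
    )
    p1 = np.where(X @ single.omega + single.bias >= 0, 1, -1)
    p2 = np.where(np.hstack([X, X]) @ doubled.omega + doubled.bias >= 0, 1, -1)
    assert (p1 == p2).all()


def test_lp_objective_matches_independent_oracle(rng):
    for _ in range(5):
        X = rng.random((10, 15))
        y = np.where(rng.random(10) < 0.5, 1.0, -1.0)
        if abs(y.sum()) == 10:
            y[0] = -y[0]
        lam = float(rng.choice([0.01, 0.1, 1.0]))
        model = fit_l1svm(X, y, lam)
        assert training_objective(model, X, y) == pytest.approx(
            oracle_objective(X, y, lam), abs=1e-8
        )


def test_hinge_feasibility_at_solution(rng):
    X = rng.random((12, 6))
    y = np.where(rng.random(12) < 0.5, 1.0, -1.0)
    y[:2] = [1.0, -1.0]
    model = fit_l1svm(X, y, 0.5)
    margins = y * (X @ model.omega + model.bias)
    xi = np.maximum(0.0, 1.0 - margins)
    assert np.all(xi >= -1e-9)
    assert np.all(margins >= 1.0 - xi - 1e-9)


def test_single_class_input_raises(rng):
    X = rng.random((6, 3))
    with pytest.raises(ClassError):
        fit_l1svm(X, np.ones(6), 0.1)


def test_sparse_prediction_equals_full_weight_prediction(rng):
    """Restricting to Γ (nonzero weights) changes nothing in the decision."""
    ds = random_dataset(rng, n_bags=8, universe=30)
    registry = FeatureRegistry.from_bags(ds.bags)
    emb = build_embedding(ds.bags, registry, "manhattan")
    y = ds.labels().astype(float)
    if abs(y.sum()) == len(y):
        pytest.skip("degenerate label draw")
    model = fit_l1svm(emb.values, y, 0.1, registry=registry, metric="manhattan")
    full = np.where(emb.values @ model.omega + model.bias >= 0, 1, -1)
    sparse = predict(model, ds.bags)
    np.testing.assert_array_equal(full, sparse)


def test_empty_gamma_predicts_bias_sign(rng):
    ds = random_dataset(rng, n_bags=3, universe=20)
    registry = FeatureRegistry.from_bags(ds.bags)
    model = L1SVMModel(
        omega=np.zeros(len(registry)), bias=-0.3, lam=1.0,
        metric="manhattan", registry=registry,
    )
    with pytest.warns(UserWarning):
        preds = predict(model, ds.bags)
    assert (preds == -1).all()


def test_prototypes_sorted_by_magnitude(rng):
    ds = random_dataset(rng, n_bags=2, universe=20)
    registry = FeatureRegistry.from_bags(ds.bags)
    n = len(registry)
    omega = np.zeros(n)
    omega[:3] = [0.0, 0.5, -1.2]
    model = L1SVMModel(omega=omega, bias=0.0, lam=1.0, metric="dice",
                       registry=registry)
    protos = prototypes(model)
    assert [r for r, _, _ in protos] == [2, 1]
    assert [s for _, _, s in protos] == [-1, 1]


def test_all_zero_model_has_no_prototypes(rng):
    ds = random_dataset(rng, n_bags=2, universe=20)
    registry = FeatureRegistry.from_bags(ds.bags)
    model = L1SVMModel(omega=np.zeros(len(registry)), bias=0.1, lam=1.0,
                       metric="dice", registry=registry)
    assert prototypes(model) == []


def test_select_lambda_tie_goes_to_largest():
    assert select_lambda((0.25, 0.5, 1.0), (0.7, 0.9, 0.9)) == 1.0
    assert select_lambda((0.25, 0.5, 1.0), (0.9, 0.7, 0.7)) == 0.25


def test_tune_single_point_grid_returns_it(rng):
    from milespharm import SynthSpec, generate

    ds, _ = generate(SynthSpec(l=20, m=60, n_range=(2, 4), seed=3))
    report = tune_lambda(ds.bags, "manhattan", grid=(0.5,), folds=2, reps=1, seed=0)
    assert report.best_lambda == 0.5
    assert report.lambda_grid == (0.5,)


def test_tuning_sparsity_trend(rng):
    """|Γ| is non-increasing in λ (Spearman correlation ≤ 0)."""
    from scipy.stats import spearmanr

    from milespharm import SynthSpec, generate

    ds, _ = generate(SynthSpec(l=30, m=80, n_range=(2, 4), seed=5))
    report = tune_lambda(ds.bags, "manhattan", grid=DEFAULT_LAMBDA_GRID[::3],
                         folds=3, reps=1, seed=1)
    rho = spearmanr(np.log(report.lambda_grid), report.prototype_counts).statistic
    assert rho <= 0 or np.isnan(rho)
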