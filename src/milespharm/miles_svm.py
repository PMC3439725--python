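"""1-norm SVM: joint feature selection and classification in the embedded space.

The classifier is linear, y = sign(ωᵀx + b), trained by minimizing the
1-norm-regularized hinge loss

    min  λ‖ω‖₁ + Σ_i ξ_i
    s.t. y_i (ωᵀ x_i + b) ≥ 1 − ξ_i,   ξ ≥ 0

which, after the standard split ω = u − v with u, v ≥ 0, is an exact linear
program solved with HiGHS.  The 1-norm penalty drives most weights to zero;
the surviving embedded features (|ω*_r| > tol) are the *prototype conformers*
Γ.  Prediction needs distances only to Γ, a small subspace of the full
embedding.

λ is tuned by replicated stratified cross-validation over a base-2 grid.
Within each fold the embedded feature space is rebuilt from the fold-training
bags only, so held-out molecules contribute no columns — the "dynamic feature
space" that keeps internal validation honest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csr_matrix, eye_array, hstack

from .data import Bag, FeatureRegistry
from .embedding import EmbeddingMatrix, bag_distances_to_prototypes, build_embedding
from .errors import ClassError, SolverError

DEFAULT_LAMBDA_GRID = tuple(2.0**k for k in range(-8, 6))
DEFAULT_TOL = 1e-8


@dataclass(frozen=True)
class L1SVMModel:
    """Fitted 1-norm SVM over a conformer feature registry."""

    omega: np.ndarray
    bias: float
    lam: float
    metric: str
    registry: FeatureRegistry
    tol: float = DEFAULT_TOL

    def gamma(self) -> np.ndarray:
        """Prototype column indices: |ω*_r| > tol."""
        return np.flatnonzero(np.abs(self.omega) > self.tol)

    def prototype_registry(self) -> FeatureRegistry:
        return self.registry.select(self.gamma())

    def prototype_weights(self) -> np.ndarray:
        return self.omega[self.gamma()]


def fit_l1svm(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    *,
    registry: FeatureRegistry | None = None,
    metric: str = "",
    tol: float = DEFAULT_TOL,
) -> L1SVMModel:
    """Solve the 1-norm SVM LP on a feature matrix (rows = training bags).

    ``registry``/``metric`` attach embedding provenance; they may be omitted
    for plain feature matrices (the classical-QSAR baseline reuses this fit
    on bag-union fingerprints).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    l, n = X.shape
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if not ((y == 1).any() and (y == -1).any()):
        raise ClassError("training labels must include both classes")

    # variables: [u (n), v (n), xi (l), b+ , b-]
    c = np.concatenate([np.full(2 * n, lam), np.ones(l), [0.0, 0.0]])
    Yx = csr_matrix(y[:, None] * X)
    A_ub = hstack(
        [-Yx, Yx, -eye_array(l, format="csr"), csr_matrix(-y[:, None]), csr_matrix(y[:, None])],
        format="csr",
    )
    b_ub = -np.ones(l)
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=(0, None), method="highs")
    if res.status != 0:
        raise SolverError(f"LP failed (status {res.status}): {res.message}")
    z = res.x
    omega = z[:n] - z[n : 2 * n]
    omega[np.abs(omega) <= tol] = 0.0
    bias = float(z[2 * n + l] - z[2 * n + l + 1])
    if registry is None:
        registry = _anonymous_registry(n, X.shape)
    return L1SVMModel(
        omega=omega, bias=bias, lam=float(lam), metric=metric, registry=registry, tol=tol
    )


def _anonymous_registry(n: int, shape) -> FeatureRegistry:
    """Placeholder registry for fits on plain (non-embedded) feature matrices."""
    from .data import Fingerprint

    fp = Fingerprint((), 1)
    return FeatureRegistry(
        tuple(("_X", f"col{r}") for r in range(n)), tuple(fp for _ in range(n)), 1
    )


def training_objective(model: L1SVMModel, X: np.ndarray, y: np.ndarray) -> float:
    """λ‖ω‖₁ + Σ hinge — the LP objective at the fitted solution."""
    margins = y * (X @ model.omega + model.bias)
    return float(
        model.lam * np.abs(model.omega).sum() + np.maximum(0.0, 1.0 - margins).sum()
    )


def decision_values(model: L1SVMModel, bags) -> np.ndarray:
    """Σ_{r∈Γ} ω*_r D(M_i, C^r) + b*, computed on prototype columns only."""
    gamma = model.gamma()
    if gamma.size == 0:
        warnings.warn("model has no prototype conformers; predicting sign(b*)")
        return np.full(len(list(bags)), model.bias)
    proto = model.registry.select(gamma)
    w = model.omega[gamma]
    vals = []
    for bag in bags:
        D = bag_distances_to_prototypes(bag, proto, model.metric)
        vals.append(float(D.min(axis=0) @ w + model.bias))
    return np.asarray(vals)


def predict(model: L1SVMModel, bags) -> np.ndarray:
    """±1 predictions per bag; sign(0) maps to +1."""
    bags = list(bags)
    vals = decision_values(model, bags)
    return np.where(vals >= 0.0, 1, -1)


def prototypes(model: L1SVMModel) -> list[tuple[int, float, int]]:
    """Prototype conformers as (registry column, ω*_r, sign), |ω| descending."""
    gamma = model.gamma()
    entries = sorted(
        ((int(r), float(model.omega[r])) for r in gamma),
        key=lambda rw: (-abs(rw[1]), rw[0]),
    )
    return [(r, w, 1 if w > 0 else -1) for r, w in entries]


# ---------------------------------------------------------------------------
# λ tuning by replicated stratified CV with a dynamic feature space


@dataclass
class TuningReport:
    lambda_grid: tuple[float, ...]
    accuracies: np.ndarray        # (n_lambda, reps) fold-mean accuracy
    medians: np.ndarray           # per-λ median over replications
    best_lambda: float
    prototype_counts: np.ndarray  # |Γ| per λ from a full-training-set fit
    metric: str
    seed: int | None
    fold_assignments: list        # per replication: list of test-bag-id folds


def select_lambda(grid, medians) -> float:
    """argmax of the median CV accuracy; ties go to the largest λ (sparser)."""
    grid = tuple(grid)
    medians = np.asarray(medians, dtype=float)
    best = max(range(len(grid)), key=lambda gi: (medians[gi], grid[gi]))
    return float(grid[best])


def _stratified_folds(bag_ids, labels, folds, rng):
    """Label-stratified fold assignment over bags."""
    bag_ids = np.asarray(bag_ids, dtype=object)
    labels = np.asarray(labels)
    assignment = np.empty(len(bag_ids), dtype=int)
    for cls in (1, -1):
        idx = np.flatnonzero(labels == cls)
        if idx.size < folds:
            raise ClassError(
                f"class {cls:+d} has {idx.size} bags; cannot stratify into {folds} folds"
            )
        idx = rng.permutation(idx)
        for f in range(folds):
            assignment[idx[f::folds]] = f
    return assignment


def tune_lambda(
    train_bags,
    metric: str,
    grid=DEFAULT_LAMBDA_GRID,
    folds: int = 5,
    reps: int = 5,
    seed: int | None = None,
    tol: float = DEFAULT_TOL,
) -> TuningReport:
    """Pick λ maximizing the median CV accuracy over replications.

    Ties go to the largest λ (the sparser model).  Each fold's embedding
    registry is built from the fold-training bags only.
    """
    bags = list(train_bags)
    grid = tuple(sorted(grid))
    if not grid:
        raise ValueError("empty lambda grid")
    labels = np.array([b.label for b in bags])
    rng = np.random.default_rng(seed)
    acc = np.zeros((len(grid), reps))
    assignments = []
    for rep in range(reps):
        fold_of = _stratified_folds([b.bag_id for b in bags], labels, folds, rng)
        assignments.append(
            [sorted(b.bag_id for b, f in zip(bags, fold_of) if f == fold)
             for fold in range(folds)]
        )
        fold_acc = np.zeros((len(grid), folds))
        for fold in range(folds):
            tr = [b for b, f in zip(bags, fold_of) if f != fold]
            te = [b for b, f in zip(bags, fold_of) if f == fold]
            registry = FeatureRegistry.from_bags(tr)  # dynamic feature space
            emb_tr = build_embedding(tr, registry, metric)
            emb_te = build_embedding(te, registry, metric)
            y_tr = np.array([b.label for b in tr], dtype=float)
            y_te = np.array([b.label for b in te])
            for gi, lam in enumerate(grid):
                model = fit_l1svm(
                    emb_tr.values, y_tr, lam, registry=registry, metric=metric, tol=tol
                )
                pred = np.where(emb_te.values @ model.omega + model.bias >= 0, 1, -1)
                fold_acc[gi, fold] = float((pred == y_te).mean())
        acc[:, rep] = fold_acc.mean(axis=1)
    medians = np.median(acc, axis=1)
    best = select_lambda(grid, medians)
    # |Γ| per λ from full-training-set fits (the Table-4-style prototype count)
    registry = FeatureRegistry.from_bags(bags)
    emb = build_embedding(bags, registry, metric)
    y = labels.astype(float)
    counts = np.array(
        [
            fit_l1svm(emb.values, y, lam, registry=registry, metric=metric, tol=tol)
            .gamma()
            .size
            for lam in grid
        ]
    )
    return TuningReport(
        lambda_grid=grid,
        accuracies=acc,
        medians=medians,
        best_lambda=best,
        prototype_counts=counts,
        metric=metric,
        seed=seed,
        fold_assignments=assignments,
    )


def fit_miles(
    train_bags, metric: str, lam: float, tol: float = DEFAULT_TOL
) -> tuple[L1SVMModel, EmbeddingMatrix]:
    """Fit the final model on the full training set at a chosen λ."""
    bags = list(train_bags)
    registry = FeatureRegistry.from_bags(bags)
    emb = build_embedding(bags, registry, metric)
    y = np.array([b.label for b in bags], dtype=float)
    model = fit_l1svm(emb.values, y, lam, registry=registry, metric=metric, tol=tol)
    return model, emb
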