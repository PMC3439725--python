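"""Classification metrics, SOM-based splitting, and classical-QSAR baselines.

The train/test split mirrors the original protocol: a Kohonen self-organizing
map clusters molecules by their bag-union pharmacophore fingerprints, and the
training set is sampled from every occupied neuron with label stratification,
so the training molecules span the same chemical domain as the test set.

Baselines operate on bag-union fingerprints (the classical-QSAR view that
discards conformer identity): a Gini decision tree with minimum leaf size 3,
a default-parameter random forest (both delegated to scikit-learn), and the
package's own 1-norm SVM fit on the union-fingerprint feature matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .data import Bag, Dataset, Fingerprint
from .errors import ClassError
from .miles_svm import DEFAULT_LAMBDA_GRID, fit_l1svm


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            tn=int(((y_true == -1) & (y_pred == -1)).sum()),
            fp=int(((y_true == -1) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == -1)).sum()),
        )

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    num = c.tp * c.tn - c.fp * c.fn
    factors = [c.tp + c.fp, c.tp + c.fn, c.tn + c.fp, c.tn + c.fn]
    if any(f == 0 for f in factors):
        return 0.0
    return float(num / np.sqrt(np.prod([float(f) for f in factors])))


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise ValueError("empty evaluation")
    return (c.tp + c.tn) / c.total


def bag_union_fingerprint(bag: Bag) -> Fingerprint:
    """Bitwise OR over the bag's conformer fingerprints (molecule-level view)."""
    bits: set[int] = set()
    for _, fp in bag.conformers:
        bits.update(fp.on_bits)
    return Fingerprint(tuple(sorted(bits)), bag.universe_size)


def union_matrix(bags) -> np.ndarray:
    """Dense molecule x bit matrix of bag-union fingerprints."""
    bags = list(bags)
    m = bags[0].universe_size
    X = np.zeros((len(bags), m))
    for i, b in enumerate(bags):
        X[i, list(bag_union_fingerprint(b).on_bits)] = 1.0
    return X


# ---------------------------------------------------------------------------
# Kohonen self-organizing map split


class SOMGrid:
    """A small rectangular Kohonen map trained online.

    Gaussian neighborhood with radius decaying linearly from max(w, h)/2 to
    1 over the epochs; learning rate decaying linearly 0.5 -> 0.01; weights
    initialized uniform [0, 1] from the seed.
    """

    def __init__(self, width: int, height: int, dim: int, seed=None):
        if width < 1 or height < 1:
            raise ValueError("grid dimensions must be >= 1")
        self.width, self.height, self.dim = width, height, dim
        self.rng = np.random.default_rng(seed)
        self.weights = self.rng.uniform(0.0, 1.0, size=(width * height, dim))
        xs, ys = np.meshgrid(np.arange(width), np.arange(height), indexing="ij")
        coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
        diff = coords[:, None, :] - coords[None, :, :]
        self._grid_d2 = (diff**2).sum(axis=2)

    def train(self, X: np.ndarray, epochs: int = 500) -> None:
        n = X.shape[0]
        r0 = max(self.width, self.height) / 2.0
        for epoch in range(epochs):
            frac = epoch / max(epochs - 1, 1)
            radius = r0 + (1.0 - r0) * frac
            lr = 0.5 + (0.01 - 0.5) * frac
            order = self.rng.permutation(n)
            for idx in order:
                x = X[idx]
                bmu = int(np.argmin(((self.weights - x) ** 2).sum(axis=1)))
                h = np.exp(-self._grid_d2[bmu] / (2.0 * radius * radius))
                self.weights += (lr * h)[:, None] * (x - self.weights)

    def assign(self, X: np.ndarray) -> np.ndarray:
        d2 = ((X[:, None, :] - self.weights[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)


def som_split(
    dataset: Dataset,
    grid: tuple[int, int] = (10, 10),
    epochs: int = 500,
    ratio: float = 0.75,
    seed=None,
) -> tuple[list[str], list[str]]:
    """SOM-clustered, label-stratified train/test split of bag ids.

    Within each occupied neuron, molecules of each label are sampled into
    the training set at the target ratio (round-half-up per cell); a global
    adjustment then nudges the overall train fraction to ``ratio``.
    """
    labels = dataset.labels()
    X = union_matrix(dataset.bags)
    rng = np.random.default_rng(seed)
    som = SOMGrid(grid[0], grid[1], X.shape[1], seed=rng.integers(2**31))
    som.train(X, epochs=epochs)
    neuron = som.assign(X)

    train_idx: list[int] = []
    test_idx: list[int] = []
    for nrn in np.unique(neuron):
        for lab in (1, -1):
            cell = np.flatnonzero((neuron == nrn) & (labels == lab))
            if cell.size == 0:
                continue
            cell = rng.permutation(cell)
            quota = int(np.floor(cell.size * ratio + 0.5))  # round half up
            train_idx.extend(cell[:quota])
            test_idx.extend(cell[quota:])

    # global adjustment toward the target ratio
    target = int(round(dataset.n_bags * ratio))
    target = min(max(target, 1), dataset.n_bags - 1)
    train_idx, test_idx = list(train_idx), list(test_idx)
    while len(train_idx) > target:
        k = int(rng.integers(len(train_idx)))
        test_idx.append(train_idx.pop(k))
    while len(train_idx) < target:
        k = int(rng.integers(len(test_idx)))
        train_idx.append(test_idx.pop(k))

    ids = [b.bag_id for b in dataset.bags]
    return (
        [ids[i] for i in sorted(train_idx)],
        [ids[i] for i in sorted(test_idx)],
    )


# ---------------------------------------------------------------------------
# Classical-QSAR baselines on bag-union fingerprints


@dataclass
class MethodReport:
    method: str
    train: ConfusionCounts
    test: ConfusionCounts

    @property
    def train_accuracy(self) -> float:
        return accuracy(self.train)

    @property
    def test_accuracy(self) -> float:
        return accuracy(self.test)

    @property
    def train_mcc(self) -> float:
        return mcc(self.train)

    @property
    def test_mcc(self) -> float:
        return mcc(self.test)


def _tune_l1svm_static(X, y, grid, folds, reps, rng):
    """λ tuning by replicated stratified CV on a fixed feature matrix."""
    from .errors import ClassError

    y = np.asarray(y)
    acc = np.zeros((len(grid), reps))
    for rep in range(reps):
        fold_of = np.empty(len(y), dtype=int)
        for cls in (1, -1):
            idx = np.flatnonzero(y == cls)
            if idx.size < folds:
                raise ClassError("too few bags per class for stratified folds")
            idx = rng.permutation(idx)
            for f in range(folds):
                fold_of[idx[f::folds]] = f
        fold_acc = np.zeros((len(grid), folds))
        for fold in range(folds):
            tr, te = fold_of != fold, fold_of == fold
            for gi, lam in enumerate(grid):
                model = fit_l1svm(X[tr], y[tr].astype(float), lam)
                pred = np.where(X[te] @ model.omega + model.bias >= 0, 1, -1)
                fold_acc[gi, fold] = (pred == y[te]).mean()
        acc[:, rep] = fold_acc.mean(axis=1)
    from .miles_svm import select_lambda

    return select_lambda(grid, np.median(acc, axis=1))


def run_baselines(
    train_bags,
    test_bags,
    methods=("decision_tree", "l1svm", "random_forest"),
    grid=DEFAULT_LAMBDA_GRID,
    folds: int = 5,
    reps: int = 5,
    seed=None,
) -> dict[str, MethodReport]:
    """Fit and score the classical models on bag-union fingerprints."""
    train_bags, test_bags = list(train_bags), list(test_bags)
    X_tr, X_te = union_matrix(train_bags), union_matrix(test_bags)
    y_tr = np.array([b.label for b in train_bags])
    y_te = np.array([b.label for b in test_bags])
    if not ((y_tr == 1).any() and (y_tr == -1).any()):
        raise ClassError("training set must contain both classes")
    rng = np.random.default_rng(seed)
    reports: dict[str, MethodReport] = {}
    for method in methods:
        if method == "decision_tree":
            clf = DecisionTreeClassifier(
                criterion="gini",
                min_samples_leaf=3,
                random_state=int(rng.integers(2**31)),
            )
            clf.fit(X_tr, y_tr)
            p_tr, p_te = clf.predict(X_tr), clf.predict(X_te)
        elif method == "random_forest":
            clf = RandomForestClassifier(random_state=int(rng.integers(2**31)))
            clf.fit(X_tr, y_tr)
            p_tr, p_te = clf.predict(X_tr), clf.predict(X_te)
        elif method == "l1svm":
            lam = _tune_l1svm_static(
                X_tr, y_tr, tuple(sorted(grid)), folds, reps,
                np.random.default_rng(int(rng.integers(2**31))),
            )
            model = fit_l1svm(X_tr, y_tr.astype(float), lam)
            p_tr = np.where(X_tr @ model.omega + model.bias >= 0, 1, -1)
            p_te = np.where(X_te @ model.omega + model.bias >= 0, 1, -1)
        else:
            raise ValueError(f"unknown baseline method {method!r}")
        reports[method] = MethodReport(
            method=method,
            train=ConfusionCounts.from_predictions(y_tr, p_tr),
            test=ConfusionCounts.from_predictions(y_te, p_te),
        )
    return reports
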