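"""Binary-fingerprint dissimilarities and the minimum-distance bag embedding.

Instance-based embedding represents each molecule (bag) by its vector of
dissimilarities to every training conformer C^r:

    D(M_i, C^r) = min_j D(C_ij, C^r)

which converts the multiple-instance problem into a standard supervised one.
Four normalized binary dissimilarity measures are provided, expressed in the
usual a/b/c/d match-count convention (a = on in both, b = on in first only,
c = on in second only, d = off in both):

    soergel         (b+c) / (a+b+c)
    dice            (b+c) / (2a+b+c)
    manhattan       (b+c) / (a+b+c+d)
    rogers_tanimoto 2(b+c) / (a+d+2(b+c))

All four have range [0, 1].  The 0/0 case (soergel and dice on two all-zero
fingerprints) is defined as distance 0: the objects are identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Bag, FeatureRegistry, Fingerprint, fingerprint_matrix
from .errors import DimensionError, IntegrityError

METRICS = ("soergel", "dice", "manhattan", "rogers_tanimoto")


@dataclass(frozen=True)
class MatchCounts:
    """Bitwise match counts between two fingerprints over one universe."""

    a: int
    b: int
    c: int
    d: int

    @classmethod
    def of(cls, fp1: Fingerprint, fp2: Fingerprint) -> "MatchCounts":
        if fp1.universe_size != fp2.universe_size:
            raise DimensionError(
                f"universe mismatch: {fp1.universe_size} != {fp2.universe_size}"
            )
        s1, s2 = fp1.as_set(), fp2.as_set()
        a = len(s1 & s2)
        b = len(s1) - a
        c = len(s2) - a
        d = fp1.universe_size - a - b - c
        return cls(a, b, c, d)


def _metric_from_counts(a, b, c, d, metric: str):
    """Vectorized metric evaluation; inputs may be arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    bc = b + c
    if metric == "soergel":
        denom = a + bc
    elif metric == "dice":
        denom = 2 * a + bc
    elif metric == "manhattan":
        denom = a + bc + d
        bc = bc + 0.0
    elif metric == "rogers_tanimoto":
        denom = a + d + 2 * bc
        bc = 2 * bc
    else:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, bc / np.where(denom > 0, denom, 1.0), 0.0)
    return out


def dissimilarity(fp1: Fingerprint, fp2: Fingerprint, metric: str) -> float:
    """Normalized dissimilarity in [0, 1] between two fingerprints."""
    m = MatchCounts.of(fp1, fp2)
    return float(_metric_from_counts(m.a, m.b, m.c, m.d, metric))


def _pairwise_distances(fps_rows, fps_cols, universe: int, metric: str) -> np.ndarray:
    """Dense distance matrix between two fingerprint collections.

    Intersection counts come from one sparse matrix product; b, c, d follow
    from the per-fingerprint popcounts and the universe size.
    """
    X = fingerprint_matrix(fps_rows, universe)
    Y = fingerprint_matrix(fps_cols, universe)
    a = np.asarray((X @ Y.T).todense(), dtype=np.int64)
    n1 = np.asarray(X.sum(axis=1)).ravel()[:, None]
    n2 = np.asarray(Y.sum(axis=1)).ravel()[None, :]
    b = n1 - a
    c = n2 - a
    d = universe - a - b - c
    return _metric_from_counts(a, b, c, d, metric)


def bag_instance_distance(
    bag: Bag, target: Fingerprint, metric: str
) -> tuple[float, int]:
    """Minimum dissimilarity from a bag to a target conformer.

    Returns the minimum and the (0-based) index of the first conformer
    attaining it; ties break toward the lowest index, which downstream
    significant-conformer sets rely on.
    """
    if bag.n_conformers == 0:  # unreachable through Bag, kept for safety
        raise IntegrityError("empty bag")
    dists = [dissimilarity(fp, target, metric) for fp in bag.fingerprints()]
    j = int(np.argmin(dists))  # np.argmin returns the first minimum
    return float(dists[j]), j


@dataclass(frozen=True)
class EmbeddingMatrix:
    """l x n bag-to-instance dissimilarities with argmin bookkeeping."""

    values: np.ndarray
    argmin_index: np.ndarray
    row_ids: tuple[str, ...]
    registry: FeatureRegistry
    metric: str

    def __post_init__(self):
        if self.values.shape != self.argmin_index.shape:
            raise DimensionError("values/argmin shape mismatch")
        if self.values.shape != (len(self.row_ids), len(self.registry)):
            raise DimensionError("embedding shape inconsistent with ids/registry")


def build_embedding(bags, registry: FeatureRegistry, metric: str) -> EmbeddingMatrix:
    """Embed bags as rows of min-distances to every registry conformer."""
    bags = list(bags)
    if not bags:
        raise IntegrityError("no bags to embed")
    universe = registry.universe_size
    for b in bags:
        if b.universe_size != universe:
            raise DimensionError(
                f"bag {b.bag_id!r} universe {b.universe_size} != registry {universe}"
            )
    all_fps = [fp for b in bags for fp in b.fingerprints()]
    D = _pairwise_distances(all_fps, registry.fingerprints, universe, metric)
    l, n = len(bags), len(registry)
    values = np.empty((l, n), dtype=float)
    argmin = np.empty((l, n), dtype=np.int64)
    row = 0
    for i, b in enumerate(bags):
        block = D[row : row + b.n_conformers]
        argmin[i] = np.argmin(block, axis=0)  # first minimum = lowest index
        values[i] = block[argmin[i], np.arange(n)]
        row += b.n_conformers
    return EmbeddingMatrix(
        values=values,
        argmin_index=argmin,
        row_ids=tuple(b.bag_id for b in bags),
        registry=registry,
        metric=metric,
    )


def bag_distances_to_prototypes(
    bag: Bag, registry: FeatureRegistry, metric: str
) -> np.ndarray:
    """(n_i x |registry|) conformer-to-prototype distance matrix for one bag."""
    return _pairwise_distances(
        list(bag.fingerprints()), registry.fingerprints, registry.universe_size, metric
    )
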