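"""Permutation-based significance analysis of pharmacophore bits.

Follows the significance-analysis-of-microarrays (SAM) recipe adapted to
binary molecule-level occurrence data.  Each bit gets a moderated two-class
t-type ranking score

    score_k = (mean_pos_k - mean_neg_k) / (se_k + s0)

where se_k is the pooled standard error of the occurrence difference and s0
a small positive stabilizer (default: the 5th percentile of the per-bit
standard errors) that keeps low-variance bits from dominating.  Selection is
two-sided: bits enriched in either class are eligible, so all ordering is on
|score|.

Reference scores come from permutations of the class labels: at each rank q,
the reference is the mean over permutations of the q-th largest permuted
|score|.  A bit is *truly significant* at a cutoff Δ when its |score| exceeds
the permutation percentile threshold and the gap between its score and the
reference at its rank exceeds Δ.  The falsely-significant count at Δ is the
median over permutations of the number of permuted scores exceeding the
smallest truly-significant true score.  Δ* is the smallest value on a
100-point grid (0 .. max gap) at which the false count reaches zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import Dataset
from .errors import ClassError, IntegrityError


def occurrence_matrix(dataset: Dataset) -> tuple[np.ndarray, np.ndarray]:
    """Molecule-level occurrence: bit present iff on in >=1 conformer.

    Returns (l x m uint8 matrix, labels in ±1).
    """
    labels = dataset.labels()
    occ = np.zeros((dataset.n_bags, dataset.bit_universe), dtype=np.uint8)
    for i, bag in enumerate(dataset.bags):
        for _, fp in bag.conformers:
            if fp.on_bits:
                occ[i, list(fp.on_bits)] = 1
    return occ, labels


def _pooled_se(occ: np.ndarray, pos_mask: np.ndarray) -> np.ndarray:
    """Pooled standard error of the mean difference for binary columns.

    For 0/1 data the class variance is n*p*(1-p)/(n-1), so everything
    follows from the class means.
    """
    n1 = int(pos_mask.sum())
    n2 = int((~pos_mask).sum())
    p1 = occ[pos_mask].mean(axis=0)
    p2 = occ[~pos_mask].mean(axis=0)
    v1 = n1 * p1 * (1 - p1) / max(n1 - 1, 1)
    v2 = n2 * p2 * (1 - p2) / max(n2 - 1, 1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / max(n1 + n2 - 2, 1)
    return np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))


def _s0_from_se(se: np.ndarray, percentile: float = 5.0) -> float:
    s0 = float(np.percentile(se, percentile))
    if s0 <= 0.0:
        # all-constant columns at the low percentile; fall back to a small
        # positive floor tied to the SE scale
        s0 = max(float(se.max()) * 1e-3, 1e-8)
    return s0


def ranking_scores(
    occ: np.ndarray, labels: np.ndarray, s0: float | None = None
) -> np.ndarray:
    """Moderated two-class t-type score per bit (signed)."""
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == -1
    if not pos.any() or not neg.any():
        raise ClassError("both classes must be present")
    se = _pooled_se(occ, pos)
    if s0 is None:
        s0 = _s0_from_se(se)
    diff = occ[pos].mean(axis=0) - occ[neg].mean(axis=0)
    return diff / (se + s0)


@dataclass
class SignificanceResult:
    scores: np.ndarray            # signed true scores per bit
    order: np.ndarray             # bit indices sorted by |score| descending
    reference: np.ndarray         # reference |score| at each rank
    threshold: float              # permutation percentile threshold on |score|
    delta_grid: np.ndarray        # 100 equally spaced cutoffs
    true_counts: np.ndarray       # truly-significant count per Δ
    false_counts: np.ndarray      # falsely-significant (median) count per Δ
    delta_star: float
    selected_bits: np.ndarray     # bit indices selected at Δ*
    s0: float
    seed: int | None
    fallback: bool = False        # Δ* fell back to the largest grid value

    def selected_at(self, delta: float) -> np.ndarray:
        """Truly-significant bit set at an arbitrary cutoff Δ."""
        mags = np.abs(self.scores)[self.order]
        gap = mags - self.reference
        mask = (mags > self.threshold) & (gap > delta)
        return np.sort(self.order[mask])


def _false_count(perm_sorted: np.ndarray, cutoff: float) -> float:
    """Median over permutations of #permuted |scores| >= cutoff."""
    counts = (perm_sorted >= cutoff).sum(axis=1)
    return float(np.median(counts))


def permutation_analysis(
    occ: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 500,
    percentile: float = 0.90,
    seed: int | None = None,
    s0: float | None = None,
) -> SignificanceResult:
    """Full SAM-style analysis: scores, references, Δ grid, and Δ* selection."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    pos = labels == 1
    if not pos.any() or not (~pos).any():
        raise ClassError("both classes must be present")
    n1 = int(pos.sum())
    l, m = occ.shape

    se = _pooled_se(occ, pos)
    if s0 is None:
        s0 = _s0_from_se(se)
    true_scores = ranking_scores(occ, labels, s0=s0)
    mags = np.abs(true_scores)
    order = np.argsort(-mags, kind="stable")
    mags_sorted = mags[order]

    # permuted scores, vectorized across permutations: each permutation is a
    # reassignment of which molecules are "positive" (class sizes preserved)
    occf = occ.astype(float)
    perm_pos = np.zeros((n_perm, l), dtype=bool)
    for p in range(n_perm):
        perm_pos[p, rng.permutation(l)[:n1]] = True
    P = perm_pos.astype(float)
    n2 = l - n1
    m1 = (P @ occf) / n1                       # (n_perm, m) positive means
    m2 = ((1.0 - P) @ occf) / n2
    v1 = n1 * m1 * (1 - m1) / max(n1 - 1, 1)
    v2 = n2 * m2 * (1 - m2) / max(n2 - 1, 1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / max(l - 2, 1)
    perm_se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    perm_scores = np.abs((m1 - m2) / (perm_se + s0))
    perm_sorted = -np.sort(-perm_scores, axis=1)  # each row descending

    reference = perm_sorted.mean(axis=0)
    threshold = float(np.percentile(perm_scores.ravel(), percentile * 100.0))

    gap = mags_sorted - reference
    max_gap = max(float(gap.max()), 0.0)
    delta_grid = np.linspace(0.0, max_gap, 100)

    above = mags_sorted > threshold
    true_counts = np.empty(100, dtype=np.int64)
    false_counts = np.empty(100, dtype=float)
    for gi, delta in enumerate(delta_grid):
        sig = above & (gap > delta)
        true_counts[gi] = int(sig.sum())
        if true_counts[gi] == 0:
            false_counts[gi] = 0.0
        else:
            cutoff = float(mags_sorted[sig].min())
            false_counts[gi] = _false_count(perm_sorted, cutoff)

    zero = np.flatnonzero(false_counts == 0)
    fallback = zero.size == 0
    if fallback:
        warnings.warn(
            "falsely-significant count never reached zero; using the largest Δ",
            stacklevel=2,
        )
        star_idx = 99
    else:
        star_idx = int(zero[0])
    delta_star = float(delta_grid[star_idx])
    sig_star = above & (gap > delta_star)
    selected = np.sort(order[sig_star])

    return SignificanceResult(
        scores=true_scores,
        order=order,
        reference=reference,
        threshold=threshold,
        delta_grid=delta_grid,
        true_counts=true_counts,
        false_counts=false_counts,
        delta_star=delta_star,
        selected_bits=selected,
        s0=s0,
        seed=seed,
        fallback=fallback,
    )


def select_delta(
    delta_grid: np.ndarray, false_counts: np.ndarray
) -> tuple[float, bool]:
    """Smallest Δ with zero falsely-significant bits (fallback: largest Δ)."""
    zero = np.flatnonzero(np.asarray(false_counts) == 0)
    if zero.size == 0:
        warnings.warn(
            "falsely-significant count never reached zero; using the largest Δ",
            stacklevel=2,
        )
        return float(delta_grid[-1]), True
    return float(delta_grid[zero[0]]), False


def select_significant_bits(
    dataset: Dataset,
    n_perm: int = 500,
    percentile: float = 0.90,
    seed: int | None = None,
) -> tuple[Dataset, SignificanceResult, dict[int, int]]:
    """Convenience wrapper: run the analysis and restrict a dataset to Δ*-selected bits."""
    occ, labels = occurrence_matrix(dataset)
    result = permutation_analysis(occ, labels, n_perm=n_perm, percentile=percentile, seed=seed)
    if result.selected_bits.size == 0:
        raise IntegrityError("significance analysis selected no bits")
    bit_map = {int(b): i for i, b in enumerate(result.selected_bits)}
    return dataset.restrict_bits(bit_map, len(bit_map)), result, bit_map
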