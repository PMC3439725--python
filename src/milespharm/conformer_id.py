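"""Significant-conformer identification and bioactive-conformer ranking.

Each prototype conformer C^r (r ∈ Γ) is won by the bag conformer closest to
it; the distinct winners form the bag's *significant conformer* set Σ, and
the prototypes won by conformer j* form its back-map Γ_{j*}.  The back-maps
partition Γ, so the per-conformer contributions

    f(C_ij*) = Σ_{r ∈ Γ_{j*}} ω*_r · D(C_ij*, C^r)

sum exactly to the bag's decision value minus the bias — each conformer's f
is its share of the classification score.  The significant conformer with
the highest f is the putative bioactive conformer.  Conformers outside Σ
contribute nothing (f = 0) and are reported with rank "N.A.".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Bag
from .embedding import bag_distances_to_prototypes
from .errors import IntegrityError
from .miles_svm import L1SVMModel


@dataclass
class ConformerReport:
    """Per-bag conformer contributions under one fitted model."""

    bag_id: str
    conformer_ids: tuple[str, ...]
    sigma: tuple[int, ...]                 # significant conformer indices (0-based)
    gamma_map: dict[int, tuple[int, ...]]  # j* -> prototype registry columns won
    contributions: np.ndarray              # f per conformer (0 outside Σ)
    ranking: tuple[int, ...]               # Σ sorted by f descending
    seeded_ids: frozenset

    @property
    def bioactive_index(self) -> int:
        """Index of the top-contributing significant conformer."""
        return self.ranking[0]

    @property
    def bioactive_id(self) -> str:
        return self.conformer_ids[self.bioactive_index]

    def rank_of(self, conformer_index: int) -> int | None:
        """Worst-rank position of a conformer's f among the bag's ranked conformers.

        Conformers outside Σ are irrelevant to the classification (f = 0 by
        convention) and get rank None ("N.A."); a conformer in Σ is ranked by
        f descending among the Σ members, ties sharing the worst rank
        (rank = #{k in Σ : f_k >= f_j}).  A unique Σ member is therefore
        rank 1 regardless of the sign of its contribution.
        """
        if conformer_index not in self.sigma:
            return None
        f = self.contributions
        return int(sum(1 for k in self.sigma if f[k] >= f[conformer_index]))


def significant_conformers(
    bag: Bag, model: L1SVMModel
) -> tuple[tuple[int, ...], dict[int, tuple[int, ...]]]:
    """Σ and the prototype back-map for one bag.

    For each prototype column r the winning conformer is the first (lowest
    index) minimizer of D(C_ij, C^r) over the bag.
    """
    gamma = model.gamma()
    if gamma.size == 0:
        raise IntegrityError("model has no prototype conformers")
    proto = model.registry.select(gamma)
    D = bag_distances_to_prototypes(bag, proto, model.metric)  # (n_i, |Γ|)
    winners = np.argmin(D, axis=0)  # first minimum => lowest conformer index
    gamma_map: dict[int, list[int]] = {}
    for col, j_star in enumerate(winners):
        gamma_map.setdefault(int(j_star), []).append(int(gamma[col]))
    sigma = tuple(sorted(gamma_map))
    return sigma, {j: tuple(rs) for j, rs in gamma_map.items()}


def contributions(bag: Bag, model: L1SVMModel) -> ConformerReport:
    """Per-conformer contributions f and the bioactive-conformer ranking."""
    sigma, gamma_map = significant_conformers(bag, model)
    gamma = model.gamma()
    proto = model.registry.select(gamma)
    w = model.omega[gamma]
    col_of = {int(r): c for c, r in enumerate(gamma)}
    D = bag_distances_to_prototypes(bag, proto, model.metric)
    f = np.zeros(bag.n_conformers)
    for j_star, won in gamma_map.items():
        cols = [col_of[r] for r in won]
        f[j_star] = float(D[j_star, cols] @ w[cols])
    ranking = tuple(sorted(sigma, key=lambda j: (-f[j], j)))
    return ConformerReport(
        bag_id=bag.bag_id,
        conformer_ids=bag.conformer_ids,
        sigma=sigma,
        gamma_map=gamma_map,
        contributions=f,
        ranking=ranking,
        seeded_ids=bag.seeded_ids,
    )


def rank_seeded(bag: Bag, model: L1SVMModel) -> dict[str, tuple[int | None, float]]:
    """Rank each seeded conformer's contribution among all n_i conformers.

    Returns {seeded_conformer_id: (rank or None, contribution)}.  Rank is
    1-based with ties sharing the worst rank; a seeded conformer outside Σ
    has contribution 0 and rank None (reported as "N.A.").
    """
    if not bag.seeded_ids:
        raise IntegrityError(f"bag {bag.bag_id!r} has no seeded conformers")
    report = contributions(bag, model)
    out = {}
    for cid in sorted(bag.seeded_ids):
        j = bag.conformer_ids.index(cid)
        out[cid] = (report.rank_of(j), float(report.contributions[j]))
    return out
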