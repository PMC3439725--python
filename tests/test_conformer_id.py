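"""Significant conformers, Eq.-6-style contributions, seeded ranking."""

import numpy as np
import pytest

from milespharm import (
    Bag,
    FeatureRegistry,
    Fingerprint,
    contributions,
    dissimilarity,
    rank_seeded,
    significant_conformers,
)
from milespharm.errors import IntegrityError
from milespharm.miles_svm import L1SVMModel, decision_values

from conftest import random_dataset, random_fingerprint


def model_from(registry, omega, bias=0.0, metric="manhattan"):
    return L1SVMModel(
        omega=np.asarray(omega, dtype=float), bias=bias, lam=0.1,
        metric=metric, registry=registry,
    )


def random_model(rng, n_proto=4, universe=20, sparse_frac=0.5):
    fps = tuple(random_fingerprint(rng, universe, 0.3) for _ in range(n_proto))
    registry = FeatureRegistry(
        tuple(("R", f"p{i}") for i in range(n_proto)), fps, universe
    )
    omega = rng.normal(size=n_proto)
    omega[rng.random(n_proto) < sparse_frac] = 0.0
    if np.all(omega == 0):
        omega[0] = 1.0
    return model_from(registry, omega, bias=float(rng.normal()))


def test_single_conformer_bag_wins_everything(rng):
    model = random_model(rng)
    bag = Bag("B", 1, (("c0", random_fingerprint(rng, 20)),))
    sigma, gmap = significant_conformers(bag, model)
    assert sigma == (0,)
    assert set(gmap[0]) == set(model.gamma())


def test_forced_winner_collects_all_prototypes():
    universe = 8
    proto_fp = Fingerprint((0, 1, 2), universe)
    registry = FeatureRegistry((("R", "p0"), ("R", "p1")),
                               (proto_fp, Fingerprint((0, 1), universe)), universe)
    model = model_from(registry, [0.5, -0.5])
    bag = Bag(
        "B", 1,
        (("far0", Fingerprint((6, 7), universe)),
         ("near", Fingerprint((0, 1, 2), universe)),
         ("far1", Fingerprint((5, 6, 7), universe))),
    )
    sigma, gmap = significant_conformers(bag, model)
    assert sigma == (1,)
    assert set(gmap[1]) == {0, 1}


def test_backmap_partitions_gamma(rng):
    for _ in range(20):
        model = random_model(rng, n_proto=6)
        n_c = int(rng.integers(1, 5))
        bag = Bag("B", 1, tuple(
            (f"c{j}", random_fingerprint(rng, 20)) for j in range(n_c)
        ))
        sigma, gmap = significant_conformers(bag, model)
        won = [r for rs in gmap.values() for r in rs]
        assert sorted(won) == sorted(model.gamma().tolist())  # partition of Γ
        assert set(gmap) == set(sigma)
        # brute-force winner check
        proto = model.registry.select(model.gamma())
        for col, r in enumerate(model.gamma()):
            dists = [dissimilarity(fp, proto.fingerprints[col], model.metric)
                     for fp in bag.fingerprints()]
            assert int(np.argmin(dists)) in gmap and r in gmap[int(np.argmin(dists))]


def test_hand_contribution_single_conformer():
    """One conformer, two prototypes, ω = (0.5, −0.2), distances (0.4, 0.1)."""
    universe = 10
    conf = Fingerprint((0, 1, 2, 3, 4), universe)
    # manhattan distances to conf: 0.4 => 4 differing bits of 10, 0.1 => 1
    p1 = Fingerprint((0, 1, 2, 3, 5, 6, 7), universe)  # adds {5,6,7}, drops {4}: 4 diffs
    p2 = Fingerprint((0, 1, 2, 3), universe)      # drops {4}: 1 diff
    assert dissimilarity(conf, p1, "manhattan") == pytest.approx(0.4)
    assert dissimilarity(conf, p2, "manhattan") == pytest.approx(0.1)
    registry = FeatureRegistry((("R", "p1"), ("R", "p2")), (p1, p2), universe)
    model = model_from(registry, [0.5, -0.2])
    bag = Bag("B", 1, (("c0", conf),))
    report = contributions(bag, model)
    assert report.contributions[0] == pytest.approx(0.5 * 0.4 - 0.2 * 0.1)  # 0.18


def test_conservation_identity(rng):
    """Σ_{j*∈Σ} f = decision value − b*, exactly (regrouped sum)."""
    for _ in range(50):
        model = random_model(rng, n_proto=5)
        n_c = int(rng.integers(1, 5))
        bag = Bag("B", 1, tuple(
            (f"c{j}", random_fingerprint(rng, 20)) for j in range(n_c)
        ))
        report = contributions(bag, model)
        total = sum(report.contributions[j] for j in report.sigma)
        decision = float(decision_values(model, [bag])[0])
        assert total == pytest.approx(decision - model.bias, abs=1e-10)


def test_dropping_non_significant_conformers_keeps_decision(rng):
    for _ in range(10):
        model = random_model(rng, n_proto=5)
        bag = Bag("B", 1, tuple(
            (f"c{j}", random_fingerprint(rng, 20)) for j in range(5)
        ))
        report = contributions(bag, model)
        kept = tuple(bag.conformers[j] for j in sorted(report.sigma))
        reduced = Bag("B", 1, kept)
        d_full = decision_values(model, [bag])[0]
        d_red = decision_values(model, [reduced])[0]
        assert d_red == pytest.approx(d_full, abs=1e-12)


def test_non_sigma_conformers_have_zero_contribution_and_na_rank(rng):
    model = random_model(rng, n_proto=3)
    bag = Bag("B", 1, tuple(
        (f"c{j}", random_fingerprint(rng, 20)) for j in range(6)
    ))
    report = contributions(bag, model)
    for j in range(6):
        if j not in report.sigma:
            assert report.contributions[j] == 0.0
            assert report.rank_of(j) is None


def test_unique_sigma_member_ranks_first(rng):
    model = random_model(rng)
    bag = Bag("B", 1, (("c0", random_fingerprint(rng, 20)),))
    report = contributions(bag, model)
    assert report.rank_of(0) == 1


def test_equal_contributions_share_worst_rank():
    universe = 6
    proto = Fingerprint((0,), universe)
    registry = FeatureRegistry(
        (("R", "p0"), ("R", "p1")), (Fingerprint((0, 1), universe),
                                     Fingerprint((2, 3), universe)), universe)
    model = model_from(registry, [1.0, 1.0])
    # c0 closest to p0, c1 closest to p1, both at the same distance
    bag = Bag("B", 1, (("c0", Fingerprint((0, 1, 4), universe)),
                       ("c1", Fingerprint((2, 3, 5), universe))))
    report = contributions(bag, model)
    f = report.contributions
    assert f[0] == pytest.approx(f[1])
    assert report.rank_of(0) == report.rank_of(1) == 2


def test_rank_seeded_conventions(rng):
    from milespharm import seed_conformer
    from conftest import random_dataset

    ds = random_dataset(rng, n_bags=3, universe=20)
    model = random_model(rng)
    bag = ds.bags[0]
    ds2 = seed_conformer(ds, bag.bag_id, random_fingerprint(rng, 20), "xtal")
    out = rank_seeded(ds2.bag(bag.bag_id), model)
    rank, contr = out["xtal"]
    report = contributions(ds2.bag(bag.bag_id), model)
    j = ds2.bag(bag.bag_id).conformer_ids.index("xtal")
    if j in report.sigma:
        assert rank is not None and contr == report.contributions[j]
    else:
        assert rank is None and contr == 0.0


def test_rank_seeded_requires_seeded_conformer(rng):
    model = random_model(rng)
    bag = Bag("B", 1, (("c0", random_fingerprint(rng, 20)),))
    with pytest.raises(IntegrityError):
        rank_seeded(bag, model)


def test_empty_model_is_rejected(rng):
    from milespharm.data import FeatureRegistry

    fps = (random_fingerprint(rng, 20),)
    registry = FeatureRegistry((("R", "p0"),), fps, 20)
    model = model_from(registry, [0.0])
    bag = Bag("B", 1, (("c0", random_fingerprint(rng, 20)),))
    with pytest.raises(IntegrityError):
        significant_conformers(bag, model)
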