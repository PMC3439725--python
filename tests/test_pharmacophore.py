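"""Pharmacophore key enumeration, binning/overlap rules, occurrence filtering."""

from itertools import combinations

import numpy as np
import pytest

from milespharm import (
    Bag,
    Dataset,
    Fingerprint,
    enumerate_keys,
    key_for_quadruplet,
    occurrence_filter,
)
from milespharm.errors import SpecError
from milespharm.pharmacophore import BinningScheme, FeaturePoint, fingerprint_dataset


def regular_tetrahedron(edge):
    v = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
    return v * (edge / np.linalg.norm(v[0] - v[1]))


def points_of(types, coords):
    return [FeaturePoint(t, tuple(x)) for t, x in zip(types, coords)]


def test_edge_exactly_one_bin_width_from_edges_gives_one_key():
    # 3.0 Å sits exactly 1.0 Å from both edges of bin [2, 4); the overlap rule
    # is strict, so no expansion occurs
    pts = points_of("DAHR", regular_tetrahedron(3.0))
    assert len(key_for_quadruplet(pts)) == 1


def test_mid_bin_overlap_expands_to_64_keys():
    # 3.5 Å is 0.5 Å from edge 4.0: each of the 6 distances matches two bins
    pts = points_of("DAHR", regular_tetrahedron(3.5))
    assert len(key_for_quadruplet(pts)) == 64


def test_out_of_range_distance_yields_no_key():
    pts = points_of("DAHR", [(0, 0, 0), (25, 0, 0), (0, 3, 0), (0, 0, 3)])
    assert key_for_quadruplet(pts) == frozenset()


def test_arity_and_coordinate_errors():
    pts = points_of("DAH", regular_tetrahedron(3.0)[:3])
    with pytest.raises(ValueError, match="4 feature points"):
        key_for_quadruplet(pts)
    with pytest.raises(ValueError, match="coordinate"):
        FeaturePoint("D", (float("nan"), 0, 0))


def test_fewer_than_four_points_give_empty_key_set():
    pts = points_of("DAH", regular_tetrahedron(3.0)[:3])
    assert enumerate_keys(pts) == frozenset()


def test_four_points_equal_single_quadruplet():
    pts = points_of("DAHR", regular_tetrahedron(3.0))
    assert enumerate_keys(pts) == key_for_quadruplet(pts)


def test_six_points_respect_combinatorial_bound(rng):
    coords = rng.uniform(0, 8, size=(6, 3))
    pts = points_of("DAHNPR", coords)
    keys = enumerate_keys(pts)
    brute = frozenset().union(
        *(key_for_quadruplet(list(quad)) for quad in combinations(pts, 4))
    )
    assert keys == brute
    assert len(keys) <= 15 * 64


def test_permutation_invariance(rng):
    coords = rng.uniform(0, 9, size=(5, 3))
    pts = points_of("DAHNP", coords)
    base = enumerate_keys(pts)
    for _ in range(5):
        perm = rng.permutation(5)
        assert enumerate_keys([pts[i] for i in perm]) == base


def test_rigid_motion_invariance(rng):
    coords = rng.uniform(0, 9, size=(5, 3))
    pts = points_of("DAHNP", coords)
    # random rotation via QR, plus translation: distances are preserved
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    moved = coords @ q.T + rng.uniform(-30, 30, size=3)
    assert enumerate_keys(points_of("DAHNP", moved)) == enumerate_keys(pts)


def test_chirality_flag_splits_mirror_images():
    coords = regular_tetrahedron(5.1)  # irregular types to avoid symmetry
    pts = points_of("DAHR", coords)
    mirror = points_of("DAHR", coords * np.array([1, 1, -1]))
    assert enumerate_keys(pts) == enumerate_keys(mirror)  # distance-only: achiral
    assert enumerate_keys(pts, chirality=True) != enumerate_keys(
        mirror, chirality=True
    )


def test_fingerprint_dataset_assigns_stable_bits(rng):
    coords = rng.uniform(0, 9, size=(4, 3))
    rows = [
        ("M1", "c1", 1, points_of("DAHR", coords)),
        ("M1", "c2", 1, points_of("DAHR", coords + 0.1)),
        ("M2", "c1", -1, points_of("DAHN", coords)),
    ]
    ds1 = fingerprint_dataset(rows)
    ds2 = fingerprint_dataset(rows)
    assert ds1.bags == ds2.bags and ds1.bit_universe == ds2.bit_universe


# ---------------------------------------------------------------------------
# occurrence filtering


def _dataset_with_bit_in_k_molecules(k, l=100, m=10):
    """Bit 0 present in k molecules; bit 1 present in all (anchor)."""
    bags = []
    for i in range(l):
        bits = (0, 1) if i < k else (1,)
        bags.append(Bag(f"M{i}", 1, ((f"c0", Fingerprint(bits, m)),)))
    return Dataset(tuple(bags), m)


def test_bit_in_4_percent_of_molecules_is_removed():
    ds = _dataset_with_bit_in_k_molecules(4)
    filtered, bit_map = occurrence_filter(ds, 0.05)
    assert 0 not in bit_map and 1 in bit_map


def test_bit_in_exactly_5_percent_is_retained():
    ds = _dataset_with_bit_in_k_molecules(5)
    filtered, bit_map = occurrence_filter(ds, 0.05)
    assert 0 in bit_map and 1 in bit_map


def test_ubiquitous_bit_is_retained():
    ds = _dataset_with_bit_in_k_molecules(100)
    _, bit_map = occurrence_filter(ds, 0.05)
    assert set(bit_map) == {0, 1}


def test_occurrence_counts_molecules_not_conformers():
    # one molecule carrying the bit in many conformers still counts once
    m = 10
    heavy = Bag("M0", 1, tuple((f"c{j}", Fingerprint((0, 1), m)) for j in range(50)))
    others = [Bag(f"M{i}", 1, (("c0", Fingerprint((1,), m)),)) for i in range(1, 100)]
    ds = Dataset((heavy, *others), m)
    _, bit_map = occurrence_filter(ds, 0.05)
    assert 0 not in bit_map  # 1/100 molecules < 5%


def test_occurrence_filter_is_idempotent(rng):
    from conftest import random_dataset

    ds = random_dataset(rng, n_bags=30, universe=60)
    once, map1 = occurrence_filter(ds, 0.1)
    twice, map2 = occurrence_filter(once, 0.1)
    assert twice.bit_universe == once.bit_universe
    assert [b.conformers for b in twice.bags] == [b.conformers for b in once.bags]


def test_all_bits_removed_raises():
    # every bit occurs in exactly one of 100 molecules: all fall below 5%
    bags = tuple(
        Bag(f"M{i}", 1, (("c0", Fingerprint((i,), 100)),)) for i in range(100)
    )
    with pytest.raises(SpecError):
        occurrence_filter(Dataset(bags, 100), 0.05)
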