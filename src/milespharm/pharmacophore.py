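"""Four-point pharmacophore fingerprint enumeration and occurrence filtering.

A pharmacophore key is a canonical arrangement of four typed feature points
(donor D, acceptor A, hydrophobe H, negative N, positive P, aromatic ring R)
together with the six pairwise inter-feature distances, discretized into
2-Å-wide bins spanning 2.0–20.0 Å.  A distance that falls strictly within
1.0 Å of an interior bin edge also matches the adjacent bin, so a single
geometric quadruplet can expand into up to 2^6 keys.  Keys are distance-only
and therefore achiral; an optional signed-volume chirality flag (off by
default) splits each key by the sign of the tetrahedron volume.

Fingerprint bits are allocated through a :class:`KeyTable` that maps canonical
keys to dense integer indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations, product
from typing import Iterable

import numpy as np

from .data import Bag, Dataset, Fingerprint
from .errors import IntegrityError, SpecError

FEATURE_TYPES = ("D", "A", "H", "N", "P", "R")


@dataclass(frozen=True)
class BinningScheme:
    """Distance bins: half-open [lo, lo+width) except the last, which is closed."""

    min_distance: float = 2.0
    max_distance: float = 20.0
    width: float = 2.0
    overlap: float = 1.0

    @property
    def n_bins(self) -> int:
        return int(round((self.max_distance - self.min_distance) / self.width))

    def bin_of(self, d: float) -> int:
        idx = int(np.floor((d - self.min_distance) / self.width))
        return min(idx, self.n_bins - 1)  # max_distance falls in the last bin

    def candidate_bins(self, d: float) -> tuple[int, ...] | None:
        """Bins matched by distance ``d``, or None if out of range."""
        if not (self.min_distance <= d <= self.max_distance):
            return None
        i = self.bin_of(d)
        lo = self.min_distance + i * self.width
        hi = lo + self.width
        bins = [i]
        # strictly-within-1.0-Å rule: an exact 1.0 Å gap does not expand
        if i > 0 and (d - lo) < self.overlap:
            bins.insert(0, i - 1)
        if i < self.n_bins - 1 and (hi - d) < self.overlap:
            bins.append(i + 1)
        return tuple(bins)


DEFAULT_BINS = BinningScheme()


@dataclass(frozen=True)
class FeaturePoint:
    """A typed pharmacophore feature at a 3D position (Å)."""

    feature_type: str
    position: tuple[float, float, float]

    def __post_init__(self):
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(
                f"feature type must be one of {FEATURE_TYPES}, got {self.feature_type!r}"
            )
        pos = tuple(float(x) for x in self.position)
        if not all(np.isfinite(pos)):
            raise ValueError(f"non-finite coordinate {pos}")
        object.__setattr__(self, "position", pos)


# Pair order of the 6 distances for points (0,1,2,3)
_PAIRS = tuple(combinations(range(4), 2))


def _canonicalize(types, bins6, chirality_sign=None):
    """Lexicographic minimum over the 24 point permutations.

    ``bins6`` is a dict {(i,j): bin} over the unordered pairs.  The canonical
    form is invariant to any reordering of the four input points.
    """
    best = None
    for perm in permutations(range(4)):
        key = tuple(types[p] for p in perm) + tuple(
            bins6[tuple(sorted((perm[i], perm[j])))] for i, j in _PAIRS
        )
        if best is None or key < best:
            best = key
    if chirality_sign is not None:
        best = best + (chirality_sign,)
    return best


def _signed_volume(positions) -> int:
    p = np.asarray(positions, dtype=float)
    v = np.linalg.det(p[1:] - p[0])
    if abs(v) < 1e-9:
        return 0
    return 1 if v > 0 else -1


def key_for_quadruplet(
    points, bins: BinningScheme = DEFAULT_BINS, chirality: bool = False
) -> frozenset:
    """Canonical keys for one 4-point arrangement (with bin-overlap expansion).

    Returns the empty set when any pairwise distance lies outside the binning
    range.  With overlap expansion each of the six distances may match one or
    two bins; the Cartesian product over the choices yields up to 64 keys.
    """
    pts = list(points)
    if len(pts) != 4:
        raise ValueError(f"exactly 4 feature points required, got {len(pts)}")
    types = tuple(p.feature_type for p in pts)
    positions = [p.position for p in pts]
    candidates = {}
    for i, j in _PAIRS:
        d = float(np.linalg.norm(np.subtract(positions[i], positions[j])))
        cand = bins.candidate_bins(d)
        if cand is None:
            return frozenset()
        candidates[(i, j)] = cand
    sign = _signed_volume(positions) if chirality else None
    keys = set()
    for choice in product(*(candidates[p] for p in _PAIRS)):
        bins6 = dict(zip(_PAIRS, choice))
        keys.add(_canonicalize(types, bins6, sign))
    return frozenset(keys)


def enumerate_keys(
    points: Iterable[FeaturePoint],
    bins: BinningScheme = DEFAULT_BINS,
    chirality: bool = False,
) -> frozenset:
    """Union of keys over all 4-point subsets of a conformer's feature points.

    Conformers with fewer than four feature points yield no keys: only
    four-feature arrangements carry enough geometry to orient a structure.
    """
    pts = list(points)
    keys: set = set()
    for quad in combinations(pts, 4):
        keys |= key_for_quadruplet(quad, bins, chirality)
    return frozenset(keys)


class KeyTable:
    """Global canonical-key <-> bit-index table.

    ``freeze`` assigns dense indices in sorted key order, so the mapping is a
    pure function of the key set and is identical across runs.
    """

    def __init__(self):
        self._keys: set = set()
        self._index: dict | None = None

    def add(self, keys) -> None:
        if self._index is not None:
            raise IntegrityError("key table already frozen")
        self._keys.update(keys)

    def freeze(self) -> None:
        self._index = {k: i for i, k in enumerate(sorted(self._keys))}

    @property
    def size(self) -> int:
        if self._index is None:
            raise IntegrityError("key table not frozen")
        return max(len(self._index), 1)

    def fingerprint(self, keys) -> Fingerprint:
        if self._index is None:
            raise IntegrityError("key table not frozen")
        bits = tuple(sorted(self._index[k] for k in keys if k in self._index))
        return Fingerprint(bits, self.size)


def fingerprint_dataset(
    conformer_points: list[tuple[str, str, int | None, list[FeaturePoint]]],
    bins: BinningScheme = DEFAULT_BINS,
    chirality: bool = False,
    provenance: str = "",
) -> Dataset:
    """Build a Dataset from per-conformer feature points.

    ``conformer_points`` rows are (bag_id, conformer_id, label, points); bag
    order and within-bag conformer order are preserved.
    """
    table = KeyTable()
    per_conf = []
    for bag_id, cid, label, points in conformer_points:
        keys = enumerate_keys(points, bins, chirality)
        table.add(keys)
        per_conf.append((bag_id, cid, label, keys))
    table.freeze()
    order: list[str] = []
    by_bag: dict[str, dict] = {}
    for bag_id, cid, label, keys in per_conf:
        if bag_id not in by_bag:
            by_bag[bag_id] = {"label": label, "conformers": []}
            order.append(bag_id)
        elif label is not None:
            by_bag[bag_id]["label"] = label
        by_bag[bag_id]["conformers"].append((cid, table.fingerprint(keys)))
    bags = tuple(
        Bag(b, by_bag[b]["label"], tuple(by_bag[b]["conformers"])) for b in order
    )
    return Dataset(bags, table.size, provenance)


def occurrence_filter(
    dataset: Dataset, min_fraction: float = 0.05
) -> tuple[Dataset, dict[int, int]]:
    """Drop bits present in fewer than ``min_fraction`` of the molecules.

    Presence is molecule-level: a bit counts once per molecule if any of its
    conformers carries it.  A bit is retained iff
    ``molecule_count / n_molecules >= min_fraction`` (the boundary fraction
    itself is kept).  Returns the reduced dataset and the old->new bit map.
    """
    if not (0.0 < min_fraction < 1.0):
        raise ValueError("min_fraction must be in (0, 1)")
    l = dataset.n_bags
    counts = np.zeros(dataset.bit_universe, dtype=np.int64)
    for bag in dataset.bags:
        present: set[int] = set()
        for _, fp in bag.conformers:
            present.update(fp.on_bits)
        if present:
            counts[np.fromiter(present, dtype=np.int64)] += 1
    retained = np.flatnonzero(counts / l >= min_fraction)
    if retained.size == 0:
        raise SpecError(
            "occurrence filter removed every bit; lower min_fraction or check input"
        )
    bit_map = {int(old): new for new, old in enumerate(retained)}
    return dataset.restrict_bits(bit_map, len(bit_map)), bit_map


# ---------------------------------------------------------------------------
# Feature-point JSONL input


def read_feature_points(path) -> list[tuple[str, str, int | None, list[FeaturePoint]]]:
    """Read per-conformer feature points from JSONL.

    One object per conformer:
    ``{"bag": id, "conformer": id, "label": ..., "points": [{"type": "D", "xyz": [x,y,z]}...]}``.
    """
    import json

    from .data import parse_label
    from .errors import ParseError

    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                points = [
                    FeaturePoint(p["type"], tuple(p["xyz"])) for p in obj["points"]
                ]
                rows.append(
                    (
                        str(obj["bag"]),
                        str(obj["conformer"]),
                        parse_label(obj.get("label")),
                        points,
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise ParseError(f"malformed feature-point record: {exc}", line=lineno)
    return rows
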