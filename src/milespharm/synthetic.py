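"""Synthetic bags of conformer fingerprints with planted witness conformers.

The generator emulates the multiple-instance axiom directly: a bag is
positive if and only if at least one of its conformers is a *witness* — a
conformer that carries (with rate ``p_w``) the bits of a designated witness
pattern on top of the background bit noise.  Negative bags contain no
witnesses, though background noise can still switch on isolated witness bits,
which is exactly what makes the minimum-distance embedding non-trivial.

Every random draw flows through one seeded generator in a fixed order
(bags -> conformers -> bits), so a spec plus seed reproduces the data set
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data import Bag, Dataset, Fingerprint
from .errors import IntegrityError, SpecError


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for the generator (defaults = the canonical fixture)."""

    l: int = 80                      # number of bags (molecules)
    balance: float = 0.5             # fraction of positive bags
    n_range: tuple[int, int] = (3, 10)  # conformers per bag, inclusive
    m: int = 400                     # bit universe size
    witness_sizes: tuple[int, ...] = (12,)  # disjoint witness pattern sizes
    p_bg: float = 0.05               # background per-bit on-rate
    p_w: float = 0.95                # witness-bit on-rate in witness conformers
    epsilon: float = 0.01            # post-hoc symmetric bit-flip noise
    witness_fraction: float = 0.25   # fraction of positive-bag conformers that are witnesses
    seed: int = 7

    def validate(self) -> None:
        if self.l < 2:
            raise SpecError("need at least 2 bags")
        if not (0.0 < self.balance < 1.0):
            raise SpecError("balance must be in (0, 1)")
        if self.n_range[0] < 1 or self.n_range[0] > self.n_range[1]:
            raise SpecError("invalid conformer-count range")
        if sum(self.witness_sizes) > self.m:
            raise SpecError("witness patterns do not fit in the bit universe")
        if not self.witness_sizes or any(s < 1 for s in self.witness_sizes):
            raise SpecError("need >=1 witness pattern of positive size")
        for rate in (self.p_bg, self.p_w, self.epsilon, self.witness_fraction):
            if not (0.0 <= rate <= 1.0):
                raise SpecError("rates must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted: labels, witness flags, witness patterns."""

    labels: dict[str, int]
    witness_flags: dict[str, frozenset[str]]   # bag_id -> witness conformer ids
    witness_sets: tuple[frozenset[int], ...]   # disjoint bit patterns

    def check_mil_axiom(self) -> None:
        for bag_id, label in self.labels.items():
            has_witness = bool(self.witness_flags.get(bag_id))
            if (label == 1) != has_witness:
                raise IntegrityError(
                    f"MIL axiom violated for bag {bag_id!r}: "
                    f"label {label:+d}, witnesses {sorted(self.witness_flags.get(bag_id, ()))}"
                )


DEFAULT_SPEC = SynthSpec()


def _draw_conformer_bits(rng, spec, witness_set: frozenset[int] | None) -> np.ndarray:
    bits = rng.random(spec.m) < spec.p_bg
    if witness_set is not None:
        idx = np.fromiter(sorted(witness_set), dtype=np.int64)
        bits[idx] |= rng.random(idx.size) < spec.p_w
    if spec.epsilon > 0:
        bits ^= rng.random(spec.m) < spec.epsilon
    return bits


def generate(spec: SynthSpec = DEFAULT_SPEC) -> tuple[Dataset, GroundTruth]:
    """Generate a labelled dataset plus its ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    remaining = list(range(spec.m))
    witness_sets = []
    for size in spec.witness_sizes:
        chosen = rng.choice(len(remaining), size=size, replace=False)
        chosen_bits = frozenset(remaining[i] for i in sorted(chosen))
        witness_sets.append(chosen_bits)
        remaining = [b for b in remaining if b not in chosen_bits]

    n_pos = int(round(spec.l * spec.balance))
    label_seq = np.array([1] * n_pos + [-1] * (spec.l - n_pos))
    rng.shuffle(label_seq)

    bags = []
    labels: dict[str, int] = {}
    flags: dict[str, frozenset[str]] = {}
    for i in range(spec.l):
        bag_id = f"M{i:03d}"
        label = int(label_seq[i])
        n_i = int(rng.integers(spec.n_range[0], spec.n_range[1] + 1))
        if label == 1:
            n_wit = max(1, int(round(spec.witness_fraction * n_i)))
            wit_positions = set(
                int(j) for j in rng.choice(n_i, size=min(n_wit, n_i), replace=False)
            )
        else:
            wit_positions = set()
        conformers = []
        wit_ids = set()
        for j in range(n_i):
            cid = f"c{j:02d}"
            if j in wit_positions:
                pattern = witness_sets[int(rng.integers(len(witness_sets)))]
                wit_ids.add(cid)
            else:
                pattern = None
            on = _draw_conformer_bits(rng, spec, pattern)
            conformers.append((cid, Fingerprint(tuple(np.flatnonzero(on)), spec.m)))
        bags.append(Bag(bag_id, label, tuple(conformers)))
        labels[bag_id] = label
        flags[bag_id] = frozenset(wit_ids)

    truth = GroundTruth(labels=labels, witness_flags=flags, witness_sets=tuple(witness_sets))
    truth.check_mil_axiom()
    dataset = Dataset(tuple(bags), spec.m, provenance=f"synthetic seed={spec.seed}")
    return dataset, truth


def witness_fingerprint(
    spec: SynthSpec, witness_set: frozenset[int], seed=None
) -> Fingerprint:
    """A fresh witness-conformer draw (the synthetic 'crystal' conformer)."""
    rng = np.random.default_rng(seed)
    on = _draw_conformer_bits(rng, spec, witness_set)
    return Fingerprint(tuple(np.flatnonzero(on)), spec.m)


def seed_conformer(
    dataset: Dataset, bag_id: str, fingerprint: Fingerprint, conformer_id: str
) -> Dataset:
    """Append an externally supplied conformer to one bag, flagged as seeded."""
    bag = dataset.bag(bag_id)
    if conformer_id in bag.conformer_ids:
        raise IntegrityError(
            f"conformer id {conformer_id!r} already present in bag {bag_id!r}"
        )
    new_bag = replace(
        bag,
        conformers=bag.conformers + ((conformer_id, fingerprint),),
        seeded_ids=bag.seeded_ids | {conformer_id},
    )
    new_bags = tuple(new_bag if b.bag_id == bag_id else b for b in dataset.bags)
    return replace(dataset, bags=new_bags)
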