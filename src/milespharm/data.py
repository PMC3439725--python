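"""Domain types and sparse fingerprint I/O.

A molecule is a *bag* of conformers; each conformer carries a sparse binary
pharmacophore fingerprint over a shared bit universe.  Fingerprints are stored
as sorted tuples of on-bit indices because realistic universes are large
(10^5-scale after occurrence filtering) while individual fingerprints are
sparse.

Two line-oriented interchange formats are supported:

* ``sparse-jsonl`` — a header line ``{"universe": m}`` followed by one JSON
  object per conformer: ``{"bag": id, "conformer": id, "label": "+1|-1|NA",
  "bits": [ints], "seeded": bool}``.
* ``sparse-tsv`` — an optional ``#universe=m`` comment, a header row, then
  columns ``bag_id  conformer_id  label  bits`` (bits comma-separated).

Activity labels are stored internally as +1 / -1 (``None`` for unknown);
input accepts ``positive``/``negative``/``1``/``0``/``-1``/``+1``/``NA``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse as sp

from .errors import (
    DimensionError,
    IntegrityError,
    LabelError,
    ParseError,
    SchemaError,
)

MODEL_SCHEMA_VERSION = 1

_LABEL_MAP = {
    "+1": 1, "1": 1, "positive": 1, "pos": 1, "active": 1,
    "-1": -1, "0": -1, "negative": -1, "neg": -1, "inactive": -1,
    "na": None, "nan": None, "none": None, "": None, "unknown": None,
}


def parse_label(raw) -> int | None:
    """Map an input label token to +1 / -1 / None (unknown)."""
    if raw is None:
        return None
    if isinstance(raw, (int, np.integer)):
        if raw in (1, -1):
            return int(raw)
        if raw == 0:
            return -1
        raise LabelError(f"integer label must be +1, -1 or 0, got {raw}")
    token = str(raw).strip().lower()
    if token not in _LABEL_MAP:
        raise LabelError(f"unrecognized label {raw!r}")
    return _LABEL_MAP[token]


def format_label(label: int | None) -> str:
    return {1: "+1", -1: "-1", None: "NA"}[label]


@dataclass(frozen=True)
class Fingerprint:
    """Sparse binary fingerprint: sorted on-bit indices over ``universe_size`` bits."""

    on_bits: tuple[int, ...]
    universe_size: int

    def __post_init__(self):
        bits = tuple(int(b) for b in self.on_bits)
        if list(bits) != sorted(set(bits)):
            bits = tuple(sorted(set(bits)))
        object.__setattr__(self, "on_bits", bits)
        if self.universe_size < 1:
            raise IntegrityError("universe_size must be >= 1")
        if bits and (bits[0] < 0 or bits[-1] >= self.universe_size):
            raise IntegrityError(
                f"bit index out of range [0, {self.universe_size}): {bits}"
            )

    @property
    def count(self) -> int:
        return len(self.on_bits)

    def as_set(self) -> frozenset[int]:
        return frozenset(self.on_bits)

    def restrict(self, bit_map: dict[int, int], new_universe: int) -> "Fingerprint":
        """Project onto a reduced universe through an old->new index map."""
        kept = sorted(bit_map[b] for b in self.on_bits if b in bit_map)
        return Fingerprint(tuple(kept), new_universe)


@dataclass(frozen=True)
class Bag:
    """A molecule: ordered conformers with fingerprints and one activity label.

    ``seeded_ids`` flags conformers inserted from outside the conformational
    sampling (the co-crystallized-conformer validation protocol).
    """

    bag_id: str
    label: int | None
    conformers: tuple[tuple[str, Fingerprint], ...]
    seeded_ids: frozenset[str] = frozenset()

    def __post_init__(self):
        if len(self.conformers) == 0:
            raise IntegrityError(f"bag {self.bag_id!r} has no conformers")
        ids = [cid for cid, _ in self.conformers]
        if len(set(ids)) != len(ids):
            raise IntegrityError(f"duplicate conformer ids in bag {self.bag_id!r}")
        sizes = {fp.universe_size for _, fp in self.conformers}
        if len(sizes) != 1:
            raise DimensionError(f"mixed universe sizes in bag {self.bag_id!r}")
        unknown = self.seeded_ids - set(ids)
        if unknown:
            raise IntegrityError(f"seeded ids not in bag {self.bag_id!r}: {unknown}")

    @property
    def n_conformers(self) -> int:
        return len(self.conformers)

    @property
    def universe_size(self) -> int:
        return self.conformers[0][1].universe_size

    @property
    def conformer_ids(self) -> tuple[str, ...]:
        return tuple(cid for cid, _ in self.conformers)

    def fingerprints(self) -> tuple[Fingerprint, ...]:
        return tuple(fp for _, fp in self.conformers)


@dataclass(frozen=True)
class Dataset:
    """A labelled collection of bags over a shared bit universe."""

    bags: tuple[Bag, ...]
    bit_universe: int
    provenance: str = ""

    def __post_init__(self):
        if len(self.bags) == 0:
            raise IntegrityError("no bags")
        ids = [b.bag_id for b in self.bags]
        if len(set(ids)) != len(ids):
            raise IntegrityError("duplicate bag ids")
        for b in self.bags:
            if b.universe_size != self.bit_universe:
                raise DimensionError(
                    f"bag {b.bag_id!r} universe {b.universe_size} != {self.bit_universe}"
                )

    @property
    def n_bags(self) -> int:
        return len(self.bags)

    @property
    def n_conformers(self) -> int:
        return sum(b.n_conformers for b in self.bags)

    def labels(self) -> np.ndarray:
        labs = [b.label for b in self.bags]
        if any(l is None for l in labs):
            raise LabelError("dataset contains unlabelled bags")
        return np.asarray(labs, dtype=int)

    def bag(self, bag_id: str) -> Bag:
        for b in self.bags:
            if b.bag_id == bag_id:
                return b
        raise IntegrityError(f"no bag {bag_id!r}")

    def subset(self, bag_ids) -> "Dataset":
        wanted = list(bag_ids)
        index = {b.bag_id: b for b in self.bags}
        missing = [i for i in wanted if i not in index]
        if missing:
            raise IntegrityError(f"unknown bag ids: {missing}")
        return replace(self, bags=tuple(index[i] for i in wanted))

    def restrict_bits(self, bit_map: dict[int, int], new_universe: int) -> "Dataset":
        new_bags = []
        for b in self.bags:
            confs = tuple(
                (cid, fp.restrict(bit_map, new_universe)) for cid, fp in b.conformers
            )
            new_bags.append(replace(b, conformers=confs))
        return Dataset(tuple(new_bags), new_universe, self.provenance)


@dataclass(frozen=True)
class FeatureRegistry:
    """The embedded feature axis: all training conformers C^r, r = 1..n.

    Order is bag order then within-bag conformer order, and is therefore
    deterministic for a given bag list.  The registry also resolves each
    column to its fingerprint so embeddings and predictions can be computed.
    """

    pairs: tuple[tuple[str, str], ...]
    fingerprints: tuple[Fingerprint, ...]
    universe_size: int

    def __post_init__(self):
        if len(self.pairs) != len(self.fingerprints):
            raise IntegrityError("registry pairs/fingerprints length mismatch")
        if len(set(self.pairs)) != len(self.pairs):
            raise IntegrityError("duplicate (bag, conformer) pairs in registry")

    @classmethod
    def from_bags(cls, bags) -> "FeatureRegistry":
        pairs, fps = [], []
        for b in bags:
            for cid, fp in b.conformers:
                pairs.append((b.bag_id, cid))
                fps.append(fp)
        if not fps:
            raise IntegrityError("registry built from zero conformers")
        return cls(tuple(pairs), tuple(fps), fps[0].universe_size)

    def __len__(self) -> int:
        return len(self.pairs)

    def select(self, indices) -> "FeatureRegistry":
        idx = list(indices)
        return FeatureRegistry(
            tuple(self.pairs[i] for i in idx),
            tuple(self.fingerprints[i] for i in idx),
            self.universe_size,
        )


def fingerprint_matrix(fps, universe: int) -> sp.csr_matrix:
    """Stack fingerprints into a sparse CSR boolean matrix (rows = conformers)."""
    indptr = [0]
    indices = []
    for fp in fps:
        indices.extend(fp.on_bits)
        indptr.append(len(indices))
    data = np.ones(len(indices), dtype=np.int32)
    return sp.csr_matrix(
        (data, np.asarray(indices, dtype=np.int64), np.asarray(indptr, dtype=np.int64)),
        shape=(len(indptr) - 1, universe),
    )


# ---------------------------------------------------------------------------
# Dataset I/O


def _records_to_dataset(records, universe, provenance) -> Dataset:
    if not records:
        raise ParseError("no bags")
    max_bit = max((bits[-1] for _, _, _, bits, _ in records if bits), default=-1)
    if universe is None:
        universe = max_bit + 1 if max_bit >= 0 else 1
    seen = set()
    order: list[str] = []
    by_bag: dict[str, dict] = {}
    for bag_id, cid, label, bits, seeded in records:
        if (bag_id, cid) in seen:
            raise IntegrityError(f"duplicate record ({bag_id!r}, {cid!r})")
        seen.add((bag_id, cid))
        if bag_id not in by_bag:
            by_bag[bag_id] = {"label": label, "conformers": [], "seeded": set()}
            order.append(bag_id)
        elif label is not None:
            if by_bag[bag_id]["label"] is None:
                by_bag[bag_id]["label"] = label
            elif by_bag[bag_id]["label"] != label:
                raise LabelError(f"conflicting labels within bag {bag_id!r}")
        by_bag[bag_id]["conformers"].append((cid, Fingerprint(tuple(bits), universe)))
        if seeded:
            by_bag[bag_id]["seeded"].add(cid)
    bags = tuple(
        Bag(
            bag_id,
            by_bag[bag_id]["label"],
            tuple(by_bag[bag_id]["conformers"]),
            frozenset(by_bag[bag_id]["seeded"]),
        )
        for bag_id in order
    )
    return Dataset(bags, universe, provenance)


def read_dataset(path, format: str = "sparse-jsonl") -> Dataset:
    """Read a Dataset from ``sparse-jsonl`` or ``sparse-tsv``."""
    if format == "sparse-jsonl":
        return _read_jsonl(path)
    if format == "sparse-tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown format {format!r}")


def _read_jsonl(path) -> Dataset:
    universe = None
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"invalid JSON: {exc}", line=lineno) from exc
            if "universe" in obj and "bag" not in obj:
                universe = int(obj["universe"])
                continue
            try:
                bag_id = str(obj["bag"])
                cid = str(obj["conformer"])
                bits = sorted(int(b) for b in obj.get("bits", []))
            except (KeyError, TypeError, ValueError) as exc:
                raise ParseError(f"malformed record: {exc}", line=lineno) from exc
            label = parse_label(obj.get("label"))
            records.append((bag_id, cid, label, bits, bool(obj.get("seeded", False))))
    return _records_to_dataset(records, universe, provenance=str(path))


def _read_tsv(path) -> Dataset:
    universe = None
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#universe="):
                universe = int(line.split("=", 1)[1])
                continue
            cols = line.split("\t")
            if cols[0] == "bag_id":  # header row
                continue
            if len(cols) < 4:
                raise ParseError(f"expected >=4 columns, got {len(cols)}", line=lineno)
            bag_id, cid, raw_label, raw_bits = cols[0], cols[1], cols[2], cols[3]
            seeded = len(cols) > 4 and cols[4].strip().lower() in ("1", "true", "yes")
            try:
                bits = sorted(int(b) for b in raw_bits.split(",") if b.strip() != "")
            except ValueError as exc:
                raise ParseError(f"bad bit list {raw_bits!r}", line=lineno) from exc
            records.append((bag_id, cid, parse_label(raw_label), bits, seeded))
    return _records_to_dataset(records, universe, provenance=str(path))


def write_dataset(dataset: Dataset, path, format: str = "sparse-jsonl") -> None:
    if format == "sparse-jsonl":
        with open(path, "w") as fh:
            fh.write(json.dumps({"universe": dataset.bit_universe}) + "\n")
            for b in dataset.bags:
                for cid, fp in b.conformers:
                    rec = {
                        "bag": b.bag_id,
                        "conformer": cid,
                        "label": format_label(b.label),
                        "bits": list(fp.on_bits),
                    }
                    if cid in b.seeded_ids:
                        rec["seeded"] = True
                    fh.write(json.dumps(rec) + "\n")
    elif format == "sparse-tsv":
        with open(path, "w") as fh:
            fh.write(f"#universe={dataset.bit_universe}\n")
            fh.write("bag_id\tconformer_id\tlabel\tbits\tseeded\n")
            for b in dataset.bags:
                for cid, fp in b.conformers:
                    bits = ",".join(str(x) for x in fp.on_bits)
                    seeded = "true" if cid in b.seeded_ids else "false"
                    fh.write(
                        f"{b.bag_id}\t{cid}\t{format_label(b.label)}\t{bits}\t{seeded}\n"
                    )
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Model I/O (schema shared with miles_svm.L1SVMModel)


def write_model(model, path) -> None:
    """Serialize an L1SVMModel to JSON (prototype columns only)."""
    omega = np.asarray(model.omega, dtype=float)
    if not np.all(np.isfinite(omega)) or not np.isfinite(model.bias):
        raise ValueError("model weights must be finite")
    gamma = model.gamma()
    payload = {
        "version": MODEL_SCHEMA_VERSION,
        "metric": model.metric,
        "lambda": model.lam,
        "bias": model.bias,
        "tol": model.tol,
        "universe": model.registry.universe_size,
        "weights": [[int(r), float(omega[r])] for r in gamma],
        "features": [list(model.registry.pairs[r]) for r in gamma],
        "prototype_bits": [list(model.registry.fingerprints[r].on_bits) for r in gamma],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_model(path):
    """Load a model written by :func:`write_model`.

    Reconstructs a Γ-only model: the registry holds just the prototype
    columns, which predicts identically to the full model.
    """
    from .miles_svm import L1SVMModel  # local import to avoid a cycle

    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise SchemaError(f"corrupted model file: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("version") != MODEL_SCHEMA_VERSION:
        raise SchemaError(
            f"unknown model schema version {payload.get('version') if isinstance(payload, dict) else payload!r}"
        )
    try:
        universe = int(payload["universe"])
        pairs = tuple((str(b), str(c)) for b, c in payload["features"])
        fps = tuple(
            Fingerprint(tuple(int(x) for x in bits), universe)
            for bits in payload["prototype_bits"]
        )
        omega = np.array([w for _, w in payload["weights"]], dtype=float)
        registry = FeatureRegistry(pairs, fps, universe)
        return L1SVMModel(
            omega=omega,
            bias=float(payload["bias"]),
            lam=float(payload["lambda"]),
            metric=str(payload["metric"]),
            registry=registry,
            tol=float(payload.get("tol", 1e-8)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"malformed model payload: {exc}") from exc
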