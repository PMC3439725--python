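import numpy as np
import pytest

from milespharm import Bag, Dataset, Fingerprint


def random_fingerprint(rng, universe=50, density=0.2) -> Fingerprint:
    on = np.flatnonzero(rng.random(universe) < density)
    return Fingerprint(tuple(on), universe)


def random_dataset(rng, n_bags=5, universe=50, max_conf=4, labelled=True) -> Dataset:
    bags = []
    for i in range(n_bags):
        n_c = int(rng.integers(1, max_conf + 1))
        confs = tuple(
            (f"c{j}", random_fingerprint(rng, universe)) for j in range(n_c)
        )
        label = int(rng.choice([1, -1])) if labelled else None
        bags.append(Bag(f"B{i}", label, confs))
    return Dataset(tuple(bags), universe)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
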