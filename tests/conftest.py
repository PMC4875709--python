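import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from csqca.dataset import CaseRecord, ConditionDef, Dataset


def make_registry(k: int, expectations=None):
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"[:k]
    expectations = expectations or ["none"] * k
    return tuple(
        ConditionDef(f"c{l}", l, e) for l, e in zip(letters, expectations)
    )


def random_dataset(k: int, n: int, seed: int, p_outcome: float = 0.5) -> Dataset:
    """A random crisp case table (uniform configurations, Bernoulli outcome)."""
    rng = np.random.default_rng(seed)
    registry = make_registry(k)
    names = [c.name for c in registry]
    cases = tuple(
        CaseRecord(
            f"case{i}",
            dict(zip(names, rng.integers(0, 2, size=k).tolist())),
            int(rng.random() < p_outcome),
        )
        for i in range(n)
    )
    return Dataset(registry, cases)


def toy_dataset(rows, k: int = 2) -> Dataset:
    """Dataset from explicit (config, outcome) pairs; ids are positional."""
    registry = make_registry(k)
    names = [c.name for c in registry]
    cases = tuple(
        CaseRecord(f"t{i}", dict(zip(names, cfg)), out)
        for i, (cfg, out) in enumerate(rows)
    )
    return Dataset(registry, cases)


@pytest.fixture(scope="session")
def table2():
    from csqca.synthetic import table2_fixture

    return table2_fixture()


@pytest.fixture(scope="session")
def table3():
    from csqca.synthetic import table3_membership_fixture

    return table3_membership_fixture()
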