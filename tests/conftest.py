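import numpy as np
import pytest

from hic3d import matrix as mat_mod
from hic3d import simulate as sim_mod
from hic3d.genome import BinnedGenome


@pytest.fixture(scope="session")
def small_genome() -> BinnedGenome:
    return BinnedGenome({"chr1": 5_000, "chr2": 3_000}, resolution=100)


@pytest.fixture(scope="session")
def default_truth():
    return sim_mod.make_truth(seed=11)


@pytest.fixture(scope="session")
def default_map(default_truth):
    """One simulated condition-1 map at the default scale, balanced, with
    its O/E transform — shared across tests that only read it."""
    raw = sim_mod.simulate_contact_map(default_truth, "condition1", seed=12)
    balanced = mat_mod.kr_balance(raw)
    oe = mat_mod.observed_over_expected(
        balanced, mat_mod.expected_by_distance(balanced))
    return {"raw": raw, "balanced": balanced, "oe": oe}


def random_symmetric(n: int, seed: int, low: float = 1.0,
                     high: float = 20.0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    a = rng.uniform(low, high, size=(n, n))
    return (a + a.T) / 2
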