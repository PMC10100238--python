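import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from avibrain.simulate import SyntheticScenario, generate_scenario, simulate_tree
from avibrain.treeio import vcv

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=20,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240617)


@pytest.fixture(scope="session")
def tree50():
    return simulate_tree(50, seed=11)


@pytest.fixture(scope="session")
def tree200():
    return simulate_tree(200, seed=13)


@pytest.fixture(scope="session")
def cov200(tree200):
    return vcv(tree200)


@pytest.fixture(scope="session")
def default_scenario_data():
    """One realisation of the default synthetic scenario."""
    scenario = SyntheticScenario(seed=77)
    return generate_scenario(scenario)


def random_tree_newick(n, rng):
    """A random non-ultrametric rooted tree via random joins."""
    nodes = [f"t{i}" for i in range(n)]
    frags = {name: f"{name}:{rng.uniform(0.1, 2.0):.6f}" for name in nodes}
    alive = list(nodes)
    while len(alive) > 2:
        i, j = sorted(rng.choice(len(alive), size=2, replace=False))
        a, b = alive[i], alive[j]
        merged = f"({frags[a]},{frags[b]}):{rng.uniform(0.1, 2.0):.6f}"
        alive.remove(a)
        alive.remove(b)
        key = f"n{len(alive)}_{a}"
        frags[key] = merged
        alive.append(key)
    newick = f"({frags[alive[0]]},{frags[alive[1]]});"
    return newick
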