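import numpy as np
import pytest

from treegnn.simulate import make_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return make_fixtures(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_tree_arrays(rng, n_leaves):
    """A random binary coalescent-shaped tree as (times, child, parent) arrays.

    Leaves are rows 0..n-1 at time 0; internal nodes follow in ascending
    time, each merging two uniformly chosen active lineages.
    """
    n_nodes = 2 * n_leaves - 1
    times = np.zeros(n_nodes)
    child, parent = [], []
    active = list(range(n_leaves))
    t = 0.0
    nxt = n_leaves
    while len(active) > 1:
        t += float(rng.exponential(10.0)) + 1e-3
        a, b = rng.choice(len(active), size=2, replace=False)
        a, b = sorted((a, b), reverse=True)
        u, v = active.pop(a), active.pop(b)
        times[nxt] = t
        child += [u, v]
        parent += [nxt, nxt]
        active.append(nxt)
        nxt += 1
    edge_index = np.array([child, parent])
    return times, edge_index


@pytest.fixture()
def random_tree_factory(rng):
    def make(n_leaves):
        return random_tree_arrays(rng, n_leaves)

    return make
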