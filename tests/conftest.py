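import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from dltrs.core import ModelParams
from dltrs.trees import discretize, parse_dated_newick


@pytest.fixture(scope="session")
def species3():
    """Three-species tree used across modules."""
    return parse_dated_newick("((A:1,B:1):1,C:2);", stem=0.2)


@pytest.fixture(scope="session")
def grid3(species3):
    return discretize(species3, 3)


@pytest.fixture(scope="session")
def cherry():
    return parse_dated_newick("(A:1,B:1);", stem=0.3)


@pytest.fixture(scope="session")
def species5():
    return parse_dated_newick(
        "(((A:0.4,B:0.4):0.3,C:0.7):0.3,(D:0.6,E:0.6):0.4);", stem=0.1
    )


@pytest.fixture(scope="session")
def theta_mid():
    return ModelParams(0.4, 0.3, 0.5, 1.0, 0.8)


def random_ultrametric_newick(rng: np.random.Generator, n_leaves: int) -> str:
    """Random ultrametric rooted binary tree by sequential coalescence."""
    nodes = [f"L{i}" for i in range(n_leaves)]
    heights = [0.0] * n_leaves
    h = 0.0
    while len(nodes) > 1:
        h += float(rng.exponential(0.5)) + 0.05
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        ha, hb = heights[i], heights[j]
        merged = f"({a}:{h - ha:.10g},{b}:{h - hb:.10g})"
        keep = [k for k in range(len(nodes)) if k not in (i, j)]
        nodes = [nodes[k] for k in keep] + [merged]
        heights = [heights[k] for k in keep] + [h]
    return nodes[0] + ";"


@pytest.fixture(scope="session")
def random_tree_factory():
    return random_ultrametric_newick


def simulate_instance(rng, species, theta, max_gene_leaves=4, min_gene_leaves=2):
    """A random (gene tree, leaf map) pair drawn from the generative
    process, suitable for small-instance oracles."""
    from dltrs.simulate import prune_extinct, relax_clock, simulate_dlt

    for _ in range(500):
        h = prune_extinct(simulate_dlt(species, theta, rng))
        if not h.usable:
            continue
        nl = len(h.pruned.leaves)
        if min_gene_leaves <= nl <= max_gene_leaves:
            relax_clock(h, theta.m, theta.cv, rng)
            return h.pruned, h.leafmap, h
    raise RuntimeError("no instance of the requested size")
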