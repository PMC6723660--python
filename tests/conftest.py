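"""Shared fixture builders for the test suite.

Small classification instances follow the package's study conditions:
standard-normal expression, planted +-1 weights on a random support,
an intercept fixed for class balance, and 10% label flips.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from nbsbm import Dataset, NetworkPrior, NoisePrior, SlabSpec


def random_network(d: int, lam: float, gam: float, seed: int, p_edge: float = 0.5,
                   prefix: str = "g") -> NetworkPrior:
    """Erdos-Renyi gene network with unit weights."""
    rng = np.random.default_rng(seed)
    genes = tuple(f"{prefix}{i}" for i in range(d))
    g = nx.Graph()
    g.add_nodes_from(genes)
    for i in range(d):
        for j in range(i + 1, d):
            if rng.random() < p_edge:
                g.add_edge(genes[i], genes[j], weight=1.0)
    return NetworkPrior.from_graph(g, lambda_=lam, gamma_=gam, nodes=genes)


def small_instance(d: int, n: int, lam: float, gam: float, seed: int,
                   effect: float = 1.0, flip: float = 0.1):
    """Tiny labelled dataset + network under the study conditions."""
    rng = np.random.default_rng(seed)
    net = random_network(d, lam, gam, seed)
    support = rng.random(d) < 0.5
    beta = np.where(support, rng.choice([-1.0, 1.0], d) * effect, 0.0)
    X = rng.standard_normal((n, d))
    margin = X @ beta
    b0 = -float(np.median(margin))
    y_clean = np.where(margin + b0 >= 0, 1.0, -1.0)
    y = np.where(rng.random(n) < flip, -y_clean, y_clean)
    if len(np.unique(y)) < 2:
        y[0] = -y[0]
    ds = Dataset.from_features(X, y, net.nodes)
    return ds, net


@pytest.fixture
def default_noise() -> NoisePrior:
    return NoisePrior()


@pytest.fixture
def empty_dataset() -> Dataset:
    return Dataset(X=np.ones((0, 3)), y=np.zeros(0), gene_names=("g0", "g1"))


def unit_slab(d: int) -> SlabSpec:
    return SlabSpec.constant(d)
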