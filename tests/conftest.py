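import itertools

import networkx as nx
import numpy as np
import pytest

from gmalign.netio import PPINetwork


def net_from_edges(name, edges, nodes=()):
    return PPINetwork.from_edges(name, edges, nodes=nodes)


@pytest.fixture
def k3():
    return net_from_edges("K3", [("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def p3():
    return net_from_edges("P3", [("x", "y"), ("y", "z")])


@pytest.fixture
def k2():
    return net_from_edges("K2", [("a", "b")])


def random_net(name, n, p, seed):
    g = nx.gnp_random_graph(n, p, seed=seed)
    return PPINetwork(name, nx.relabel_nodes(g, {i: f"{name}{i:03d}" for i in g}))


def brute_force_assignment(weights):
    """Exhaustive maximum-weight assignment over all permutations.

    Returns the optimal total weight for a (possibly rectangular) matrix,
    assigning every node of the smaller side.
    """
    w = np.asarray(weights, dtype=float)
    transposed = False
    if w.shape[0] > w.shape[1]:
        w = w.T
        transposed = True
    n, m = w.shape
    best = -np.inf
    for cols in itertools.permutations(range(m), n):
        total = sum(w[i, c] for i, c in enumerate(cols))
        best = max(best, total)
    return best


def centered_mcs_size(g1, g2, c1, c2):
    """Brute-force |V|+|E| of the largest common subgraph mapping c1 to c2."""
    n1 = [x for x in g1.nodes() if x != c1]
    n2 = [x for x in g2.nodes() if x != c2]
    best = 1
    for s in range(0, min(len(n1), len(n2)) + 1):
        for sub1 in itertools.combinations(n1, s):
            nodes1 = (c1,) + sub1
            e1 = [
                (a, b)
                for a, b in itertools.combinations(nodes1, 2)
                if g1.has_edge(a, b)
            ]
            for sub2 in itertools.permutations(n2, s):
                mapping = dict(zip(nodes1, (c2,) + sub2))
                edges = sum(
                    1 for a, b in e1 if g2.has_edge(mapping[a], mapping[b])
                )
                best = max(best, s + 1 + edges)
    return best
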