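"""Synthetic network-pair benchmarks with known ground truth.

The generator emulates the situation the aligner faces on real PPI data: a
source network, a relabelled copy perturbed by edge rewiring and by extra
nodes attached preferentially, and a sparse table of pairwise sequence
scores that is statistically correlated with the true node correspondence
(high "bit-scores" for most true pairs, low scores for random decoy pairs).
All randomness flows from one integer seed through a single generator
stream, so a pair is fully reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .netio import PPINetwork, SeqSimTable

#: Raw-score ranges for informative (true-pair) and decoy sequence scores,
#: on a BLAST bit-score-like scale.
SIGNAL_SCORE_RANGE = (100.0, 200.0)
NOISE_SCORE_RANGE = (10.0, 50.0)


@dataclass
class SyntheticPair:
    """A generated network pair with its ground truth and sequence scores."""

    net1: PPINetwork
    net2: PPINetwork
    truth: dict  # V1 node -> V2 node, injective, covers all of V1
    seqsim: SeqSimTable
    config: dict = field(default_factory=dict)
    n_edges_rewired: int = 0

    def write(self, out_dir) -> None:
        """Emit net1.tsv, net2.tsv, truth.tsv and seqsim.tsv."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for net, fname in ((self.net1, "net1.tsv"), (self.net2, "net2.tsv")):
            with open(out / fname, "w") as fh:
                for u, v in net.graph.edges():
                    fh.write(f"{u}\t{v}\n")
        with open(out / "truth.tsv", "w") as fh:
            for u in sorted(self.truth):
                fh.write(f"{u}\t{self.truth[u]}\n")
        with open(out / "seqsim.tsv", "w") as fh:
            for (u, v), raw in sorted(self.seqsim.scores.items()):
                evalue = 10.0 ** (-min(raw, 180.0))
                fh.write(f"{u}\t{v}\t{raw:.3f}\t{evalue:.3e}\n")


def caterpillar_graph(n: int) -> nx.Graph:
    """A labelled caterpillar tree on ``n`` nodes with distinct leg counts.

    Spine nodes carry increasing numbers of legs (0, 1, 2, ...), giving a
    degree-distinguishable family: node neighbourhood profiles are unique,
    which makes exact isomorphism recovery possible from topology alone.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    g = nx.Graph()
    node = 0
    spine = [0]
    g.add_node(0)
    legs = 1
    while g.number_of_nodes() < n:
        node += 1
        g.add_edge(spine[-1], node)
        spine.append(node)
        for _ in range(legs):
            if g.number_of_nodes() >= n:
                break
            node += 1
            g.add_edge(spine[-1], node)
        legs += 1
    return g


def _base_graph(n1: int, model: str, model_params: dict, rng: np.random.Generator) -> nx.Graph:
    if model == "erdos_renyi":
        p = model_params.get("p", 0.05)
        g = nx.gnp_random_graph(n1, p, seed=int(rng.integers(2**31)))
    elif model == "duplication_divergence":
        p = model_params.get("p", 0.4)
        g = nx.duplication_divergence_graph(n1, p, seed=int(rng.integers(2**31)))
    elif model == "caterpillar":
        g = caterpillar_graph(n1)
    else:
        raise ValueError(f"unknown model {model!r}")
    if g.number_of_edges() == 0:
        raise ValueError(f"model {model!r} produced an empty edge set")
    return g


def generate_pair(
    n1: int,
    model: str = "erdos_renyi",
    model_params: dict | None = None,
    rewire_rate: float = 0.0,
    extra_nodes: int = 0,
    seq_signal: float = 0.9,
    seq_noise_pairs: int | None = None,
    seed: int = 0,
) -> SyntheticPair:
    """Generate a perturbed network pair with ground-truth mapping.

    ``net2`` is a randomly relabelled copy of ``net1`` with
    floor(rewire_rate * |E1|) edges removed and the same number of random
    non-edges added, plus ``extra_nodes`` additional nodes attached by
    preferential attachment.  Each true pair receives a high raw sequence
    score with probability ``seq_signal``; ``seq_noise_pairs`` decoy pairs
    (default: n1) receive low scores.  Deterministic given ``seed``.
    """
    if n1 < 2:
        raise ValueError("n1 must be >= 2")
    if not (0.0 <= rewire_rate <= 1.0):
        raise ValueError("rewire_rate must lie in [0, 1]")
    model_params = dict(model_params or {})
    if seq_noise_pairs is None:
        seq_noise_pairs = n1
    rng = np.random.default_rng(seed)

    base = _base_graph(n1, model, model_params, rng)
    width = max(4, len(str(n1 + extra_nodes)))
    names1 = [f"p{i:0{width}d}" for i in range(n1)]
    perm = rng.permutation(n1)
    names2 = [f"q{int(perm[i]):0{width}d}" for i in range(n1)]
    truth = dict(zip(names1, names2))

    g1 = nx.relabel_nodes(base, dict(enumerate(names1)), copy=True)
    # rebuild in identifier order so node order is deterministic
    net1 = PPINetwork.from_edges("synthetic-1", sorted(map(sorted, g1.edges())), nodes=names1)

    g2 = nx.Graph()
    g2.add_nodes_from(sorted(names2))
    for u, v in net1.graph.edges():
        g2.add_edge(truth[u], truth[v])

    # rewiring: remove random edges, add the same number of random non-edges
    n_rewire = math.floor(rewire_rate * net1.n_edges)
    if n_rewire:
        edges = sorted(map(tuple, map(sorted, g2.edges())))
        drop_idx = rng.choice(len(edges), size=n_rewire, replace=False)
        for i in drop_idx:
            g2.remove_edge(*edges[int(i)])
        nodes2 = sorted(g2.nodes())
        added = 0
        while added < n_rewire:
            u, v = (nodes2[int(i)] for i in rng.integers(len(nodes2), size=2))
            if u == v or g2.has_edge(u, v):
                continue
            g2.add_edge(u, v)
            added += 1

    # extra nodes attached by preferential attachment
    for j in range(extra_nodes):
        new = f"x{j:0{width}d}"
        nodes2 = sorted(g2.nodes())
        weights = np.array([g2.degree(v) + 1.0 for v in nodes2])
        weights /= weights.sum()
        n_links = min(2, len(nodes2))
        targets = rng.choice(len(nodes2), size=n_links, replace=False, p=weights)
        g2.add_node(new)
        for t in targets:
            g2.add_edge(new, nodes2[int(t)])

    net2 = PPINetwork("synthetic-2", g2)

    # correlated sequence scores: signal on true pairs, noise on decoys
    scores: dict = {}
    lo_s, hi_s = SIGNAL_SCORE_RANGE
    lo_n, hi_n = NOISE_SCORE_RANGE
    for u in names1:
        if rng.random() < seq_signal:
            scores[(u, truth[u])] = float(rng.uniform(lo_s, hi_s))
    all2 = sorted(g2.nodes())
    placed = 0
    attempts = 0
    while placed < seq_noise_pairs and attempts < 50 * seq_noise_pairs:
        attempts += 1
        u = names1[int(rng.integers(n1))]
        v = all2[int(rng.integers(len(all2)))]
        if v == truth[u] or (u, v) in scores:
            continue
        scores[(u, v)] = float(rng.uniform(lo_n, hi_n))
        placed += 1
    seqsim = SeqSimTable(scores=scores, mode="bitscore")

    return SyntheticPair(
        net1=net1,
        net2=net2,
        truth=truth,
        seqsim=seqsim,
        config={
            "n1": n1,
            "model": model,
            "model_params": model_params,
            "rewire_rate": rewire_rate,
            "extra_nodes": extra_nodes,
            "seq_signal": seq_signal,
            "seq_noise_pairs": seq_noise_pairs,
            "seed": seed,
        },
        n_edges_rewired=n_rewire,
    )
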