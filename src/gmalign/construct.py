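"""Stage 1: anchor selection and seed-and-extend matching construction.

Anchors are node pairs that simultaneously have high composite similarity
(S(u,v) >= tau) and high degree (min{d(u), d(v)} >= delta, with delta the
larger of the two networks' average degrees).  The initial matching is then
grown outwards from the anchors with a max-priority queue over the local
expansion similarity: popping the best unmatched neighbour-pair, matching
it, and enqueueing its own neighbour cross-product until the queue empties.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .simscore import ExpansionScorer, SimilarityMatrix


@dataclass
class AlignParams:
    """Tunable parameters of the aligner.

    alpha balances structure vs sequence (0 = topology only); theta balances
    neighbourhood topology vs plain degree inside the structural score; k is
    the neighbourhood hop radius; tau is the anchor similarity threshold
    (generally >= 0.5); delta is the anchor degree threshold, derived from
    the networks' average degrees when left as None; patience is the number
    of consecutive non-improving refinement attempts tolerated before
    stopping.
    """

    alpha: float = 0.0
    theta: float = 0.5
    k: int = 2
    tau: float = 0.5
    delta: float | None = None
    patience: int = 5
    seed: int = 0
    anchor_fallback: bool = True
    skip_zero_expansion: bool = False
    tau_quantile: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.theta <= 1.0):
            raise ValueError("alpha and theta must lie in [0, 1]")
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")

    def effective_delta(self, net1, net2) -> float:
        if self.delta is not None:
            return self.delta
        return max(net1.mean_degree, net2.mean_degree)


class Matching:
    """An injective set of (V1-node, V2-node) pairs.

    Maintains the forward partial map f: V1 -> V2 and its inverse; adding a
    pair that reuses a node on either side raises.
    """

    def __init__(self, pairs=()):
        self._fwd: dict = {}
        self._bwd: dict = {}
        for u, v in pairs:
            self.add(u, v)

    def add(self, u, v) -> None:
        if u in self._fwd:
            raise ValueError(f"{u!r} already matched to {self._fwd[u]!r}")
        if v in self._bwd:
            raise ValueError(f"{v!r} already matched to {self._bwd[v]!r}")
        self._fwd[u] = v
        self._bwd[v] = u

    @property
    def pairs(self) -> set:
        return set(self._fwd.items())

    @property
    def matched1(self) -> set:
        """R1: matched nodes of the first network."""
        return set(self._fwd)

    @property
    def matched2(self) -> set:
        """R2: matched nodes of the second network."""
        return set(self._bwd)

    def image(self, u):
        """f(u), or None if u is unmatched."""
        return self._fwd.get(u)

    def preimage(self, v):
        return self._bwd.get(v)

    def has1(self, u) -> bool:
        return u in self._fwd

    def has2(self, v) -> bool:
        return v in self._bwd

    def copy(self) -> "Matching":
        m = Matching()
        m._fwd = dict(self._fwd)
        m._bwd = dict(self._bwd)
        return m

    def __len__(self) -> int:
        return len(self._fwd)

    def __contains__(self, pair) -> bool:
        u, v = pair
        return self._fwd.get(u) == v

    def __eq__(self, other) -> bool:
        return isinstance(other, Matching) and self._fwd == other._fwd

    def __repr__(self) -> str:
        return f"Matching({len(self)} pairs)"


def _ranked_pairs(s: SimilarityMatrix):
    """All (score, u, v) sorted by score non-increasing, ties lexicographic."""
    n1, n2 = s.values.shape
    flat = s.values.ravel()
    # lexsort keys: last key is primary
    order = np.lexsort((np.arange(n1 * n2), -flat))
    for idx in order:
        i, j = divmod(int(idx), n2)
        yield flat[idx], s.rows[i], s.cols[j]


def effective_tau(s: SimilarityMatrix, net1, net2, params: AlignParams) -> float:
    """The anchor threshold actually applied.

    Default is the fixed ``params.tau``; alternatively ``tau_quantile`` sets
    tau to that quantile of S over the pairs passing the degree filter.
    """
    if params.tau_quantile is None:
        return params.tau
    delta = params.effective_delta(net1, net2)
    d1 = np.array([net1.degree(u) for u in s.rows], dtype=float)
    d2 = np.array([net2.degree(v) for v in s.cols], dtype=float)
    mask = np.minimum.outer(d1, d2) >= delta
    if not mask.any():
        return params.tau
    return float(np.quantile(s.values[mask], params.tau_quantile))


def select_anchors(
    s: SimilarityMatrix, net1, net2, params: AlignParams
) -> Matching:
    """Greedy anchor selection over pairs ranked by composite similarity.

    A pair (u, v) is accepted iff min{d(u), d(v)} >= delta, S(u,v) >= tau,
    and neither node is already anchored.  May return an empty matching.
    """
    delta = params.effective_delta(net1, net2)
    tau = effective_tau(s, net1, net2, params)
    anchors = Matching()
    for score, u, v in _ranked_pairs(s):
        if score < tau:
            break  # ranked non-increasing: nothing below can pass
        if min(net1.degree(u), net2.degree(v)) < delta:
            continue
        if anchors.has1(u) or anchors.has2(v):
            continue
        anchors.add(u, v)
    return anchors


def best_pair(s: SimilarityMatrix):
    """The highest-scoring pair, ties broken lexicographically by (u, v)."""
    for score, u, v in _ranked_pairs(s):
        return u, v
    raise ValueError("empty similarity matrix")


def expand_matching(
    anchors: Matching,
    net1,
    net2,
    scorer: ExpansionScorer,
    skip_zero: bool = False,
) -> Matching:
    """Grow a matching outwards from the anchors (priority-queue expansion).

    The queue is keyed on the local expansion similarity, with ties broken
    by (u, v) identifier order for reproducibility.  Stale entries (either
    endpoint already matched) are discarded at pop time; the queue may hold
    duplicates.  Nodes unreachable from any anchor stay unmatched here.
    """
    m = anchors.copy()
    heap: list = []

    def push_neighbors(u, v):
        for nu in net1.neighbors(u):
            if m.has1(nu):
                continue
            for nv in net2.neighbors(v):
                if m.has2(nv):
                    continue
                sc = scorer.score(nu, nv)
                if skip_zero and sc <= 0.0:
                    continue
                heapq.heappush(heap, (-sc, nu, nv))

    for u, v in sorted(anchors.pairs):
        push_neighbors(u, v)
    while heap:
        _, u, v = heapq.heappop(heap)
        if m.has1(u) or m.has2(v):
            continue
        m.add(u, v)
        push_neighbors(u, v)
    return m


def construct_matching(
    net1, net2, s: SimilarityMatrix, scorer: ExpansionScorer, params: AlignParams
) -> Matching:
    """Anchor selection followed by expansion; the full first stage.

    If no pair passes the anchor conditions and ``anchor_fallback`` is on
    (the default), the single highest-similarity pair seeds the expansion so
    that the matching can still grow; in strict mode an empty anchor set
    yields an empty matching.
    """
    anchors = select_anchors(s, net1, net2, params)
    if len(anchors) == 0 and params.anchor_fallback and s.values.size:
        anchors = Matching([best_pair(s)])
    return expand_matching(anchors, net1, net2, scorer, params.skip_zero_expansion)
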