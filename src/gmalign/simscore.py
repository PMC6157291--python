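"""Node similarity scores combining local, spectral, degree and sequence terms.

The composite node similarity between u in G1 and v in G2 is

    S(u,v) = (1 - alpha) * S_str(u,v) + alpha * S_seq(u,v)
    S_str  = (1 - theta) * S_t + theta * S_d
    S_t    = S_l * S_g

where S_l compares the induced k-neighbourhood subgraphs of u and v, S_g is
a Laplacian-spectral similarity (inner product of absolute eigenvector
rows), S_d = min(d(u), d(v)) / max(d(u), d(v)) compares plain degrees, and
S_seq is the max-normalised pairwise sequence score.  All scores lie in
[0, 1].

The local score for neighbourhood subgraphs g_u^k, g_v^k is

    S_l(u,v) = (n_min + 1 + D(u,v))^2
               / ((|V(g_u^k)| + |E(g_u^k)|) * (|V(g_v^k)| + |E(g_v^k)|))
    D(u,v)   = (min{d(u), d(v)} + sum_i min{d_{1,i}, d_{2,i}}) / 2

with n_min = min(|N_k(u)|, |N_k(v)|) and d_{s,i} the non-increasing degree
sequences of the two neighbourhoods.  Member degrees are taken within the
induced neighbourhood subgraph: then D(u,u) = |E(g_u^k)| exactly, so S_l is
1 on isomorphic neighbourhoods whose centers correspond, and S_l <= 1
always (each sorted-min sum is bounded by either subgraph's edge count).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.linalg
import scipy.sparse.linalg

from .netio import PPINetwork, SeqSimTable

logger = logging.getLogger(__name__)

#: Above this node count the full dense eigendecomposition is replaced by an
#: iterative top-c approximation (see :func:`spectral_decompose`).
DENSE_EIG_CAP = 3000
#: Maximum number of eigenpairs retained by the iterative solver.
APPROX_C_CAP = 500


# ---------------------------------------------------------------------------
# Local topological similarity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NeighborhoodProfile:
    """Summary of the induced k-neighbourhood subgraph of one node.

    ``degseq`` holds the degrees of the neighbourhood members (center
    excluded) sorted non-increasingly; by default these are degrees within
    the induced subgraph (``degree_scope="subgraph"``), which is what makes
    the local score equal 1 on isomorphic neighbourhoods.
    """

    center: object
    k: int
    n_k: frozenset
    subgraph_nodes: int
    subgraph_edges: int
    degseq: tuple
    degree: int  # center degree under the chosen scope (= full-graph for k >= 1)

    @property
    def size_term(self) -> int:
        """|V(g^k)| + |E(g^k)|, the denominator contribution."""
        return self.subgraph_nodes + self.subgraph_edges


def neighborhood_profile(
    net: PPINetwork, v, k: int, degree_scope: str = "subgraph"
) -> NeighborhoodProfile:
    """Profile of the induced subgraph over all nodes within k hops of ``v``."""
    if v not in net.graph:
        raise KeyError(f"node {v!r} not in network {net.name!r}")
    if k < 0:
        raise ValueError("k must be >= 0")
    if degree_scope not in ("subgraph", "full"):
        raise ValueError(f"unknown degree_scope {degree_scope!r}")
    reach = nx.single_source_shortest_path_length(net.graph, v, cutoff=k)
    n_k = frozenset(u for u in reach if u != v)
    sub = net.graph.subgraph(n_k | {v})
    if degree_scope == "subgraph":
        degseq = tuple(sorted((sub.degree(u) for u in n_k), reverse=True))
        center_degree = sub.degree(v)  # equals the full degree for k >= 1
    else:
        degseq = tuple(sorted((net.degree(u) for u in n_k), reverse=True))
        center_degree = net.degree(v)
    return NeighborhoodProfile(
        center=v,
        k=k,
        n_k=n_k,
        subgraph_nodes=sub.number_of_nodes(),
        subgraph_edges=sub.number_of_edges(),
        degseq=degseq,
        degree=center_degree,
    )


def local_similarity(p1: NeighborhoodProfile, p2: NeighborhoodProfile) -> float:
    """Local topological similarity S_l of two neighbourhood profiles."""
    if p1.k != p2.k:
        raise ValueError("profiles built with different k")
    n_min = min(len(p1.n_k), len(p2.n_k))
    d = (
        min(p1.degree, p2.degree)
        + sum(min(a, b) for a, b in zip(p1.degseq[:n_min], p2.degseq[:n_min]))
    ) / 2.0
    return (n_min + 1 + d) ** 2 / (p1.size_term * p2.size_term)


def profiles(net: PPINetwork, k: int, degree_scope: str = "subgraph") -> dict:
    """Neighbourhood profiles for every node of the network."""
    return {v: neighborhood_profile(net, v, k, degree_scope) for v in net.nodes}


# ---------------------------------------------------------------------------
# Global (spectral) topological similarity
# ---------------------------------------------------------------------------


@dataclass
class SpectralDecomposition:
    """Laplacian eigendecomposition with eigenvalues sorted non-increasingly.

    ``ubar`` holds the element-wise absolute values of the orthonormal
    eigenvectors (columns ordered to match the eigenvalues); taking absolute
    values resolves the sign ambiguity of eigenvectors.  ``approximate`` is
    True when only the top eigenpairs were computed by an iterative solver.
    """

    nodes: list
    eigenvalues: np.ndarray
    ubar: np.ndarray
    approximate: bool = False


def _sort_spectrum(vals: np.ndarray, ubar: np.ndarray, tol: float = 1e-9):
    """Order columns by eigenvalue (non-increasing), breaking near-ties
    lexicographically by the absolute eigenvector components so the result
    does not depend on solver-internal ordering within an eigenspace."""
    order = sorted(
        range(len(vals)),
        key=lambda j: (-round(vals[j] / tol) * tol, tuple(ubar[:, j])),
    )
    return vals[order], ubar[:, order]


def spectral_decompose(
    net: PPINetwork,
    dense_cap: int = DENSE_EIG_CAP,
    c_cap: int = APPROX_C_CAP,
) -> SpectralDecomposition:
    """Eigendecompose the Laplacian L = D - A of a network.

    Networks up to ``dense_cap`` nodes get the full symmetric dense
    decomposition; larger ones get the ``min(c_cap, n-1)`` largest
    eigenpairs from an iterative Lanczos solver and are flagged
    ``approximate``.
    """
    n = net.n_nodes
    if n == 0:
        raise ValueError("empty network")
    if n <= dense_cap:
        lap = net.laplacian()
        vals, vecs = scipy.linalg.eigh(lap)
        approx = False
    else:
        lap_sparse = nx.laplacian_matrix(net.graph, nodelist=net.nodes).astype(float)
        k = min(c_cap, n - 1)
        vals, vecs = scipy.sparse.linalg.eigsh(lap_sparse, k=k, which="LA")
        approx = True
        logger.info(
            "%s: using iterative top-%d spectral approximation (n=%d)",
            net.name, k, n,
        )
    vals, ubar = _sort_spectrum(np.asarray(vals, dtype=float), np.abs(vecs))
    return SpectralDecomposition(
        nodes=net.nodes, eigenvalues=vals, ubar=ubar, approximate=approx
    )


def global_similarity(
    dec1: SpectralDecomposition, dec2: SpectralDecomposition
) -> np.ndarray:
    """Spectral similarity matrix S_g = Ubar1' @ Ubar2'^T.

    Only the columns for the largest c = min(n1, n2) eigenvalues are
    retained (fewer if either decomposition is approximate).  Entries are
    clipped to [0, 1] against floating-point overshoot.
    """
    c = min(dec1.ubar.shape[1], dec2.ubar.shape[1])
    sg = dec1.ubar[:, :c] @ dec2.ubar[:, :c].T
    return np.clip(sg, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Composite similarity
# ---------------------------------------------------------------------------


@dataclass
class SimilarityMatrix:
    """Dense |V1| x |V2| score matrix with entries in [0, 1]."""

    rows: list
    cols: list
    values: np.ndarray
    kind: str = "S"

    def __post_init__(self):
        self._row_index = {u: i for i, u in enumerate(self.rows)}
        self._col_index = {v: j for j, v in enumerate(self.cols)}

    def get(self, u, v) -> float:
        return float(self.values[self._row_index[u], self._col_index[v]])


def degree_similarity(d_u: int, d_v: int) -> float:
    """S_d = min(d_u, d_v) / max(d_u, d_v).

    The 0/0 case (both nodes isolated) is defined as 1 — two isolated nodes
    are a perfect trivial match — and exactly one isolated node scores 0.
    """
    if d_u == 0 and d_v == 0:
        return 1.0
    if d_u == 0 or d_v == 0:
        return 0.0
    return min(d_u, d_v) / max(d_u, d_v)


def local_similarity_matrix(
    net1: PPINetwork, net2: PPINetwork, k: int = 2, degree_scope: str = "subgraph"
) -> SimilarityMatrix:
    p1 = profiles(net1, k, degree_scope)
    p2 = profiles(net2, k, degree_scope)
    vals = np.empty((net1.n_nodes, net2.n_nodes))
    for i, u in enumerate(net1.nodes):
        pu = p1[u]
        for j, v in enumerate(net2.nodes):
            vals[i, j] = local_similarity(pu, p2[v])
    return SimilarityMatrix(net1.nodes, net2.nodes, vals, kind="S_l")


def degree_similarity_matrix(net1: PPINetwork, net2: PPINetwork) -> SimilarityMatrix:
    d1 = np.array([net1.degree(u) for u in net1.nodes], dtype=float)
    d2 = np.array([net2.degree(v) for v in net2.nodes], dtype=float)
    lo = np.minimum.outer(d1, d2)
    hi = np.maximum.outer(d1, d2)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(hi > 0, lo / hi, 1.0)
    return SimilarityMatrix(net1.nodes, net2.nodes, vals, kind="S_d")


def sequence_similarity_matrix(
    net1: PPINetwork, net2: PPINetwork, seqsim: SeqSimTable | None
) -> SimilarityMatrix:
    vals = np.zeros((net1.n_nodes, net2.n_nodes))
    if seqsim is not None and not seqsim.is_empty:
        col = {v: j for j, v in enumerate(net2.nodes)}
        row = {u: i for i, u in enumerate(net1.nodes)}
        for (u, v), raw in seqsim.scores.items():
            vals[row[u], col[v]] = raw / seqsim.global_max
    return SimilarityMatrix(net1.nodes, net2.nodes, vals, kind="S_seq")


def _effective_alpha(alpha: float, seqsim: SeqSimTable | None) -> float:
    if alpha > 0 and (seqsim is None or seqsim.is_empty):
        logger.warning("no sequence similarity data: forcing alpha=0")
        return 0.0
    return alpha


def node_similarity(
    net1: PPINetwork,
    net2: PPINetwork,
    seqsim: SeqSimTable | None = None,
    alpha: float = 0.0,
    theta: float = 0.5,
    k: int = 2,
    degree_scope: str = "subgraph",
    dense_cap: int = DENSE_EIG_CAP,
) -> SimilarityMatrix:
    """Composite similarity S = (1-alpha) * [(1-theta) S_l S_g + theta S_d] + alpha S_seq."""
    if not (0.0 <= alpha <= 1.0 and 0.0 <= theta <= 1.0):
        raise ValueError("alpha and theta must lie in [0, 1]")
    alpha = _effective_alpha(alpha, seqsim)
    sl = local_similarity_matrix(net1, net2, k, degree_scope).values
    sg = global_similarity(
        spectral_decompose(net1, dense_cap=dense_cap),
        spectral_decompose(net2, dense_cap=dense_cap),
    )
    sd = degree_similarity_matrix(net1, net2).values
    sseq = sequence_similarity_matrix(net1, net2, seqsim).values
    s_str = (1.0 - theta) * (sl * sg) + theta * sd
    vals = (1.0 - alpha) * s_str + alpha * sseq
    return SimilarityMatrix(net1.nodes, net2.nodes, np.clip(vals, 0.0, 1.0), kind="S")


class ExpansionScorer:
    """Lazy per-pair expansion similarity used while growing the matching.

    Identical to the composite node similarity except that the spectral
    factor is dropped (the expansion is local):

        S_exp(u,v) = (1-alpha) * [(1-theta) S_l + theta S_d] + alpha S_seq

    Scores are computed on demand and cached per pair, never materialised as
    a dense matrix.
    """

    def __init__(
        self,
        net1: PPINetwork,
        net2: PPINetwork,
        seqsim: SeqSimTable | None = None,
        alpha: float = 0.0,
        theta: float = 0.5,
        k: int = 2,
        degree_scope: str = "subgraph",
    ):
        if not (0.0 <= alpha <= 1.0 and 0.0 <= theta <= 1.0):
            raise ValueError("alpha and theta must lie in [0, 1]")
        self.net1, self.net2 = net1, net2
        self.seqsim = seqsim
        self.alpha = _effective_alpha(alpha, seqsim)
        self.theta = theta
        self.k = k
        self.degree_scope = degree_scope
        self._profiles1: dict = {}
        self._profiles2: dict = {}
        self._cache: dict = {}

    def _profile(self, side: int, v) -> NeighborhoodProfile:
        cache = self._profiles1 if side == 1 else self._profiles2
        if v not in cache:
            net = self.net1 if side == 1 else self.net2
            cache[v] = neighborhood_profile(net, v, self.k, self.degree_scope)
        return cache[v]

    def score(self, u, v) -> float:
        key = (u, v)
        if key in self._cache:
            return self._cache[key]
        sl = local_similarity(self._profile(1, u), self._profile(2, v))
        sd = degree_similarity(self.net1.degree(u), self.net2.degree(v))
        s = (1.0 - self.alpha) * ((1.0 - self.theta) * sl + self.theta * sd)
        if self.alpha > 0:
            s += self.alpha * self.seqsim.normalized(u, v)
        s = min(max(s, 0.0), 1.0)
        self._cache[key] = s
        return s

    __call__ = score
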