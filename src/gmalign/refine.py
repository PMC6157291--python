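"""Stage 2: iterative refinement by random minimal vertex covers.

One refinement step fixes the matched part of a random minimal vertex cover
(H1, with image H2) and re-solves the rest: every refinable pair (u, v) with
u outside H1 and v outside H2 gets the weight

    w(u, v) = | M[N(u) & H1] & (N(v) & H2) |

— the number of edges that would be conserved through the frozen cover if u
were matched to v — and a maximum-weight bipartite assignment (Hungarian
method) replaces the refinable part:

    M*(H1) = (M & (H1 x H2)) | M_b.

Because the matched refinable nodes lie in the independent set, all of
their conserved edges run into H1 and are counted by w, and M's own
restriction is a feasible assignment; hence with unit sequence scores the
conserved-edge count never decreases across a step.  The loop alternates
covers drawn on either network (fair coin per iteration) and stops after
``patience`` consecutive attempts without strict score improvement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .construct import AlignParams, Matching
from .evalmetrics import matching_score


def minimal_vertex_cover(net, rng: np.random.Generator) -> set:
    """Draw a random minimal vertex cover of the network.

    Nodes are visited in a uniformly random order and added iff they still
    cover at least one uncovered edge (tracked by per-node uncovered-edge
    counters initialised to the degrees, so the construction is O(|E|)).
    A pruning pass then removes, in random order and until fixpoint, any
    cover node all of whose neighbours are inside the cover; every survivor
    therefore has a private uncovered neighbour, which is exactly
    minimality.
    """
    nodes = net.nodes
    uncovered = {u: net.degree(u) for u in nodes}
    cover: set = set()
    for idx in rng.permutation(len(nodes)):
        u = nodes[int(idx)]
        if uncovered[u] <= 0:
            continue
        cover.add(u)
        for w in net.neighbors(u):
            if w not in cover:
                uncovered[w] -= 1
        uncovered[u] = 0
    # prune to minimality
    changed = True
    while changed:
        changed = False
        members = sorted(cover)
        for idx in rng.permutation(len(members)):
            c = members[int(idx)]
            if c not in cover:
                continue
            if all(w in cover for w in net.neighbors(c)):
                cover.discard(c)
                changed = True
    return cover


def is_vertex_cover(net, cover: set) -> bool:
    return all(u in cover or v in cover for u, v in net.graph.edges())


def is_minimal_cover(net, cover: set) -> bool:
    """Cover where every member has at least one neighbour outside it."""
    if not is_vertex_cover(net, cover):
        return False
    return all(
        any(w not in cover for w in net.neighbors(c)) or net.degree(c) == 0
        for c in cover
    )


@dataclass
class VertexCoverPartition:
    """A minimal vertex cover split into frozen and refinable parts.

    ``side`` says which network the cover was drawn on ("G1" or "G2").
    ``h_cov`` is the matched part of the cover on that side, ``h_img`` its
    image under the matching on the other side; both are frozen during one
    refinement step.  All remaining nodes are refinable.
    """

    side: str
    cover: set
    independent: set
    h_cov: set
    h_img: set


def partition(m: Matching, net1, net2, side: str, cover: set) -> VertexCoverPartition:
    """Split nodes into frozen (matched cover) and refinable parts."""
    if side not in ("G1", "G2"):
        raise ValueError(f"side must be 'G1' or 'G2', got {side!r}")
    cover_net = net1 if side == "G1" else net2
    if not is_vertex_cover(cover_net, cover):
        raise ValueError("given node set is not a vertex cover")
    if side == "G1":
        h_cov = cover & m.matched1
        h_img = {m.image(u) for u in h_cov}
    else:
        h_cov = cover & m.matched2
        h_img = {m.preimage(v) for v in h_cov}
    return VertexCoverPartition(
        side=side,
        cover=set(cover),
        independent=cover_net.node_set - set(cover),
        h_cov=h_cov,
        h_img=h_img,
    )


@dataclass
class BipartiteWeightMatrix:
    """Integer weights over refinable V1 rows x refinable V2 columns."""

    rows: list  # V1 nodes, sorted
    cols: list  # V2 nodes, sorted
    weights: np.ndarray


def refinement_weights(
    part: VertexCoverPartition, net1, net2, m: Matching
) -> BipartiteWeightMatrix:
    """w(u,v) = number of frozen matched edges gained by matching u with v."""
    # frozen pairs viewed from G1's side: (h1 in V1) -> (h2 in V2); for a
    # cover drawn on G2 the roles swap symmetrically and the weight formula
    # is unchanged.
    if part.side == "G1":
        h1, h2 = part.h_cov, part.h_img
    else:
        h1, h2 = part.h_img, part.h_cov
    rows = sorted(net1.node_set - h1)
    cols = sorted(net2.node_set - h2)
    col_index = {v: j for j, v in enumerate(cols)}
    weights = np.zeros((len(rows), len(cols)), dtype=np.int64)
    for i, u in enumerate(rows):
        # images (in h2) of u's frozen matched neighbours
        targets = [m.image(x) for x in net1.neighbors(u) if x in h1]
        for y in targets:
            for v in net2.neighbors(y):
                j = col_index.get(v)
                if j is not None:
                    weights[i, j] += 1
    return BipartiteWeightMatrix(rows=rows, cols=cols, weights=weights)


def max_weight_assignment(w: BipartiteWeightMatrix) -> Matching:
    """Maximum-weight bipartite assignment over the refinable nodes.

    Every node on the smaller side is assigned (zero-weight pairs are
    allowed).  Among maximum-weight assignments, ties are broken toward the
    lexicographically earliest (row, column) pairs by adding a perturbation
    small enough never to change the optimal total of the integer weights.
    """
    n, mcols = w.weights.shape
    if n == 0 or mcols == 0:
        return Matching()
    size = n * mcols
    rank = np.arange(size, dtype=float).reshape(n, mcols)
    eps = 0.25 / (size * size + 1)
    perturbed = w.weights.astype(float) + (size - rank) * eps
    row_ind, col_ind = linear_sum_assignment(perturbed, maximize=True)
    return Matching((w.rows[i], w.cols[j]) for i, j in zip(row_ind, col_ind))


def refine_once(m: Matching, part: VertexCoverPartition, net1, net2) -> Matching:
    """One refinement step: frozen cover pairs plus a fresh assignment."""
    wmat = refinement_weights(part, net1, net2, m)
    mb = max_weight_assignment(wmat)
    frozen1 = part.h_cov if part.side == "G1" else part.h_img
    out = Matching((u, m.image(u)) for u in sorted(frozen1))
    for u, v in sorted(mb.pairs):
        out.add(u, v)
    return out


def complete_matching(m: Matching, net1, net2) -> Matching:
    """Assign leftover V1 nodes to leftover V2 nodes (identifier order)."""
    out = m.copy()
    free1 = sorted(net1.node_set - m.matched1)
    free2 = sorted(net2.node_set - m.matched2)
    for u, v in zip(free1, free2):
        out.add(u, v)
    return out


def refine_loop(
    m0: Matching,
    net1,
    net2,
    seqsim=None,
    params: AlignParams | None = None,
    rng: np.random.Generator | None = None,
) -> Matching:
    """Iterate random-cover refinement until patience is exhausted.

    Each iteration draws the cover on G1 or G2 with equal probability,
    builds the partition/weights/assignment, and accepts the candidate iff
    its matching score strictly improves.  With alpha = 0 or no sequence
    data the score is the plain conserved-edge count.  A final completion
    pass assigns any still-unmatched V1 nodes so the mapping is total when
    |V1| <= |V2|.
    """
    params = params or AlignParams()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    score_seq = None if (params.alpha == 0 or seqsim is None or seqsim.is_empty) else seqsim

    def score(m):
        return matching_score(m, net1, net2, score_seq)

    incumbent = m0
    best = score(m0)
    fails = 0
    while fails < params.patience:
        side = "G1" if rng.random() < 0.5 else "G2"
        cover_net = net1 if side == "G1" else net2
        cover = minimal_vertex_cover(cover_net, rng)
        part = partition(incumbent, net1, net2, side, cover)
        candidate = refine_once(incumbent, part, net1, net2)
        cand_score = score(candidate)
        if cand_score > best:
            incumbent, best = candidate, cand_score
            fails = 0
        else:
            fails += 1
    return complete_matching(incumbent, net1, net2)
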