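"""Topological and biological quality measures for a network alignment.

Topological: the sequence-weighted matching score, edge correctness
EC = |f(E1)| / |E1|, the node and edge fractions LCC = |V_m| / |V1| and
LCCe = |E_m| / |E1| of the largest connected component of the
conserved-edge graph, and the symmetric substructure score
S3 = |f(E1)| / (|E1| + |E(G2(f(V1)))| - |f(E1)|).

Biological: functional consistency FC_{>=a} (fraction of aligned pairs
sharing at least a GO terms, over |V1|) and the average functional
similarity AFS per GO category, using Resnik term similarity with the
best-match-average mixing strategy.  Conserved pathway substructures map a
pathway's proteins through the alignment and intersect the validated
interaction sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx

from .netio import AnnotationSet, OntologyDAG, PPINetwork, SeqSimTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Topological measures
# ---------------------------------------------------------------------------


def conserved_edge_graph(m, net1: PPINetwork, net2: PPINetwork) -> nx.Graph:
    """The subgraph of G1 whose edges are conserved under the matching.

    An edge (u, v) of G1 is conserved when both endpoints are matched and
    (f(u), f(v)) is an edge of G2.  Nodes are all matched V1 nodes, so
    isolated matched nodes appear as singleton components.
    """
    g = nx.Graph()
    g.add_nodes_from(m.matched1)
    for u, v in net1.graph.edges():
        fu, fv = m.image(u), m.image(v)
        if fu is not None and fv is not None and net2.has_edge(fu, fv):
            g.add_edge(u, v)
    return g


def conserved_edges(m, net1: PPINetwork, net2: PPINetwork) -> int:
    """|f(E1)|: the number of conserved edges."""
    return conserved_edge_graph(m, net1, net2).number_of_edges()


def matching_score(
    m, net1: PPINetwork, net2: PPINetwork, seqsim: SeqSimTable | None = None
) -> float:
    """Sequence-weighted count of conserved edges (the alignment objective).

    Each conserved G1 edge (u1, u2) contributes
    seq(u1, f(u1)) * seq(u2, f(u2)) with max-normalised sequence scores;
    without sequence data every factor is 1 and the score equals the
    conserved-edge count.
    """
    total = 0.0
    for u1, u2 in net1.graph.edges():
        v1, v2 = m.image(u1), m.image(u2)
        if v1 is None or v2 is None or not net2.has_edge(v1, v2):
            continue
        if seqsim is None:
            total += 1.0
        else:
            total += seqsim.normalized(u1, v1) * seqsim.normalized(u2, v2)
    return total


def edge_correctness(m, net1: PPINetwork, net2: PPINetwork) -> float:
    """EC = conserved edges / |E1|."""
    if net1.n_edges == 0:
        raise ValueError("EC undefined: the smaller network has no edges")
    return conserved_edges(m, net1, net2) / net1.n_edges


def lcc_stats(m, net1: PPINetwork, net2: PPINetwork):
    """(LCC, LCCe, |V_m|, |E_m|) of the largest conserved component.

    The component is the largest connected component of the conserved-edge
    graph by node count; ties prefer more edges, then the lexicographically
    smallest node set.
    """
    if net1.n_edges == 0:
        raise ValueError("LCCe undefined: the smaller network has no edges")
    g = conserved_edge_graph(m, net1, net2)
    if g.number_of_nodes() == 0:
        return 0.0, 0.0, 0, 0
    best = min(
        (g.subgraph(c) for c in nx.connected_components(g)),
        key=lambda s: (-s.number_of_nodes(), -s.number_of_edges(),
                       sorted(s.nodes())),
    )
    v_m, e_m = best.number_of_nodes(), best.number_of_edges()
    return v_m / net1.n_nodes, e_m / net1.n_edges, v_m, e_m


def s3(m, net1: PPINetwork, net2: PPINetwork) -> float:
    """Symmetric substructure score.

    S3 = |f(E1)| / (|E1| + |E(G2(f(V1)))| - |f(E1)|), where the middle term
    counts the edges G2 induces on the image of the matched nodes.
    """
    if net1.n_edges == 0:
        raise ValueError("S3 undefined: the smaller network has no edges")
    cons = conserved_edges(m, net1, net2)
    image = [m.image(u) for u in m.matched1]
    induced = net2.graph.subgraph(image).number_of_edges()
    return cons / (net1.n_edges + induced - cons)


def node_correctness(m, truth: dict) -> float:
    """Fraction of ground-truth pairs recovered by the matching."""
    if not truth:
        raise ValueError("empty ground-truth mapping")
    hits = sum(1 for u, v in truth.items() if m.image(u) == v)
    return hits / len(truth)


# ---------------------------------------------------------------------------
# Biological measures
# ---------------------------------------------------------------------------


def functional_consistency(
    m,
    net1: PPINetwork,
    ann: AnnotationSet,
    a: int = 1,
    category: str | None = None,
) -> float:
    """FC_{>=a}: fraction of aligned pairs sharing at least ``a`` GO terms.

    Terms are pooled across the BP/MF/CC categories by default (pass
    ``category`` to restrict).  The denominator is |V1|.
    """
    if a < 1:
        raise ValueError("a must be >= 1")
    count = 0
    for u, v in m.pairs:
        shared = ann.terms(u, category) & ann.terms(v, category)
        if len(shared) >= a:
            count += 1
    return count / net1.n_nodes


class ResnikSimilarity:
    """Resnik term similarity over an annotation corpus.

    The information content of a term t is IC(t) = -ln p(t), where p(t) is
    the fraction of annotated corpus proteins carrying t or any descendant
    of t.  The similarity of two terms is the maximum IC over their common
    ancestors; the root has IC 0.
    """

    def __init__(self, dag: OntologyDAG, ann: AnnotationSet, category: str,
                 corpus=None):
        self.dag = dag
        self.category = category
        proteins = ann.annotated(category) if corpus is None else set(corpus)
        counts: dict = {}
        n_annotated = 0
        n_skipped = 0
        for p in proteins:
            terms = ann.terms(p, category)
            closure: set = set()
            for t in terms:
                if t not in dag.terms:
                    n_skipped += 1
                    continue
                closure |= dag.ancestors(t)
            if not closure:
                continue
            n_annotated += 1
            for t in closure:
                counts[t] = counts.get(t, 0) + 1
        if n_skipped:
            logger.warning(
                "%d annotation(s) use terms absent from the ontology; skipped",
                n_skipped,
            )
        self.n_annotated = n_annotated
        self.ic = {
            t: -math.log(c / n_annotated) for t, c in counts.items()
        } if n_annotated else {}

    def term_sim(self, t1: str, t2: str) -> float:
        if t1 not in self.dag.terms or t2 not in self.dag.terms:
            return 0.0
        common = self.dag.ancestors(t1) & self.dag.ancestors(t2)
        if not common:
            return 0.0
        return max(self.ic.get(t, 0.0) for t in common)

    def protein_sim(self, terms1, terms2) -> float:
        """Best-match-average similarity of two term sets."""
        t1 = [t for t in terms1 if t in self.dag.terms]
        t2 = [t for t in terms2 if t in self.dag.terms]
        if not t1 or not t2:
            return 0.0
        sims = [[self.term_sim(a, b) for b in t2] for a in t1]
        row_best = sum(max(row) for row in sims) / len(t1)
        col_best = sum(max(sims[i][j] for i in range(len(t1)))
                       for j in range(len(t2))) / len(t2)
        return (row_best + col_best) / 2.0


def afs(
    m,
    net1: PPINetwork,
    net2: PPINetwork,
    ann: AnnotationSet,
    dag: OntologyDAG,
    category: str,
    denominator: str = "annotated",
) -> float:
    """Average functional similarity of the alignment in one GO category.

    Sums the Resnik/BMA protein similarity S_c(u, f(u)) over matched V1
    proteins.  ``denominator="annotated"`` divides by the number of
    annotated V1 proteins (unannotated proteins contribute nothing and are
    excluded); ``denominator="v1"`` divides by |V1|.  The information
    content corpus is the union of both networks' annotated proteins in the
    category.
    """
    if denominator not in ("annotated", "v1"):
        raise ValueError("denominator must be 'annotated' or 'v1'")
    corpus = (ann.annotated(category) & (net1.node_set | net2.node_set)) or None
    resnik = ResnikSimilarity(dag, ann, category, corpus=corpus)
    total = 0.0
    annotated1 = {u for u in net1.nodes if ann.terms(u, category)}
    for u in annotated1:
        v = m.image(u)
        if v is None:
            continue
        total += resnik.protein_sim(ann.terms(u, category), ann.terms(v, category))
    if denominator == "v1":
        denom = net1.n_nodes
    else:
        denom = len(annotated1)
    if denom == 0:
        return 0.0
    return total / denom


# ---------------------------------------------------------------------------
# Conserved pathway substructures
# ---------------------------------------------------------------------------


@dataclass
class PathwayPair:
    """Two same-function pathways plus their validated interaction sets."""

    name1: str
    name2: str
    proteins1: set
    proteins2: set
    interactions1: set = field(default_factory=set)  # frozensets of V1 pairs
    interactions2: set = field(default_factory=set)


def conserved_substructure(m, pp: PathwayPair):
    """Common nodes and validated common interactions of a pathway pair.

    Common nodes are pathway-1 proteins whose image lies in pathway 2;
    common interactions are validated pathway-1 interactions between common
    nodes whose image is a validated pathway-2 interaction.
    """
    common_nodes = {u for u in pp.proteins1 if m.image(u) in pp.proteins2}
    common_edges = set()
    for pair in pp.interactions1:
        u, v = tuple(pair)
        if u in common_nodes and v in common_nodes:
            if frozenset((m.image(u), m.image(v))) in pp.interactions2:
                common_edges.add(frozenset((u, v)))
    return common_nodes, common_edges


# ---------------------------------------------------------------------------
# Combined report
# ---------------------------------------------------------------------------


@dataclass
class AlignmentReport:
    """All quality measures of one alignment, JSON-serialisable."""

    score: float
    conserved_edges: int
    ec: float
    lcc: float
    lcce: float
    s3: float
    v_m: int
    e_m: int
    fc: dict = field(default_factory=dict)  # a -> FC_{>=a}
    afs: dict = field(default_factory=dict)  # category -> AFS_c

    def to_dict(self) -> dict:
        return {
            "score": self.score,
            "conserved_edges": self.conserved_edges,
            "EC": self.ec,
            "LCC": self.lcc,
            "LCCe": self.lcce,
            "S3": self.s3,
            "V_m": self.v_m,
            "E_m": self.e_m,
            "FC": {str(a): v for a, v in self.fc.items()},
            "AFS": dict(self.afs),
        }


def build_report(
    m,
    net1: PPINetwork,
    net2: PPINetwork,
    seqsim: SeqSimTable | None = None,
    ann: AnnotationSet | None = None,
    dag: OntologyDAG | None = None,
    fc_thresholds=(1, 2, 3, 4, 5),
    afs_denominator: str = "annotated",
) -> AlignmentReport:
    """Evaluate a matching with every applicable measure."""
    lcc, lcce, v_m, e_m = lcc_stats(m, net1, net2)
    report = AlignmentReport(
        score=matching_score(m, net1, net2, seqsim),
        conserved_edges=conserved_edges(m, net1, net2),
        ec=edge_correctness(m, net1, net2),
        lcc=lcc,
        lcce=lcce,
        s3=s3(m, net1, net2),
        v_m=v_m,
        e_m=e_m,
    )
    if ann is not None:
        report.fc = {
            a: functional_consistency(m, net1, ann, a) for a in fc_thresholds
        }
        if dag is not None:
            report.afs = {
                c: afs(m, net1, net2, ann, dag, c, afs_denominator)
                for c in ("BP", "MF", "CC")
            }
    return report
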