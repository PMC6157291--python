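"""Readers and writers for the file formats used in PPI network alignment.

Formats are deliberately plain: whitespace-delimited edge lists for
networks, a BLAST-tabular subset (``id1 id2 bitscore evalue``) for pairwise
sequence similarities, two-column TSV for node mappings, a three/four column
TSV for GO annotations, and an OBO 1.2 subset (``[Term]`` / ``id`` / ``is_a``
/ ``namespace``) for the ontology.  Identifier comparison is exact,
case-sensitive string match throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: GO annotation categories: biological process, molecular function,
#: cellular component.
CATEGORIES = ("BP", "MF", "CC")

_NAMESPACE_TO_CATEGORY = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}


class ParseError(ValueError):
    """Raised for malformed or empty input files."""


# ---------------------------------------------------------------------------
# PPI networks
# ---------------------------------------------------------------------------


class PPINetwork:
    """A simple undirected graph whose nodes are protein identifiers.

    Self-loops and duplicate edges are forbidden; node order is the order
    of first appearance, which fixes the row/column order of every matrix
    derived from the network (adjacency, Laplacian, similarity matrices).
    """

    def __init__(self, name: str, graph: nx.Graph | None = None):
        self.name = name
        self.graph = graph if graph is not None else nx.Graph()
        if any(u == v for u, v in self.graph.edges()):
            raise ValueError(f"network {name!r} contains a self-loop")

    @classmethod
    def from_edges(cls, name: str, edges, nodes=()) -> "PPINetwork":
        g = nx.Graph()
        for u in nodes:
            g.add_node(u)
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop {u!r}")
            g.add_edge(u, v)
        return cls(name, g)

    # -- basic accessors ----------------------------------------------------

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes())

    @property
    def node_set(self) -> set:
        return set(self.graph.nodes())

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def mean_degree(self) -> float:
        """2|E|/|V|: the average degree of the network."""
        if self.n_nodes == 0:
            return 0.0
        return 2.0 * self.n_edges / self.n_nodes

    def degree(self, u) -> int:
        return self.graph.degree(u)

    def neighbors(self, u) -> list:
        return list(self.graph.neighbors(u))

    def has_edge(self, u, v) -> bool:
        return self.graph.has_edge(u, v)

    def laplacian(self):
        """Dense Laplacian L = D - A with rows/columns in node order."""
        return nx.laplacian_matrix(self.graph, nodelist=self.nodes).toarray().astype(float)

    def __len__(self) -> int:
        return self.n_nodes

    def __repr__(self) -> str:
        return f"PPINetwork({self.name!r}, |V|={self.n_nodes}, |E|={self.n_edges})"


def read_network(path, name: str) -> PPINetwork:
    """Read a two-column edge list into a :class:`PPINetwork`.

    Lines starting with ``#`` and blank lines are ignored.  Self-loops are
    dropped with a warning (homodimers occur in PPI data but the model graph
    is simple); duplicate and reversed-duplicate edges are collapsed.
    """
    path = Path(path)
    g = nx.Graph()
    n_selfloops = 0
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            n_lines += 1
            u, v = fields
            if u == v:
                n_selfloops += 1
                g.add_node(u)
                continue
            g.add_node(u)
            g.add_node(v)
            g.add_edge(u, v)
    if n_lines == 0:
        raise ParseError(f"{path}: no edges found")
    if n_selfloops:
        logger.warning("%s: dropped %d self-loop(s)", path, n_selfloops)
    return PPINetwork(name, g)


def write_network(net: PPINetwork, path) -> None:
    with open(path, "w") as fh:
        for u, v in net.graph.edges():
            fh.write(f"{u}\t{v}\n")


# ---------------------------------------------------------------------------
# Sequence similarity
# ---------------------------------------------------------------------------

#: Minimum representable BLAST e-value; smaller (including 0) is clamped here
#: so that -log10(evalue) caps at 180.
EVALUE_FLOOR = 1e-180


@dataclass
class SeqSimTable:
    """Sparse pairwise raw sequence-similarity scores seq(u, v) >= 0.

    Keys are ordered ``(V1-node, V2-node)`` pairs; absent pairs read as 0.
    ``global_max`` is the normaliser max_{i,j} seq(i,j); it is ``None`` when
    the table is empty, in which case the normalised score is all-zero.
    """

    scores: dict = field(default_factory=dict)
    mode: str = "bitscore"
    global_max: float | None = None

    def __post_init__(self):
        if self.global_max is None and self.scores:
            self.global_max = max(self.scores.values())

    def raw(self, u, v) -> float:
        return self.scores.get((u, v), 0.0)

    def normalized(self, u, v) -> float:
        """seq(u,v) / max seq, in [0, 1]; 0 everywhere for an empty table."""
        if not self.global_max:
            return 0.0
        return self.raw(u, v) / self.global_max

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def is_empty(self) -> bool:
        return not self.scores or not self.global_max


def evalue_to_raw(evalue: float) -> float:
    """-log10 of an e-value, clamped to [0, 180]."""
    if evalue >= 1.0:
        return 0.0
    return -math.log10(max(evalue, EVALUE_FLOOR))


def read_seqsim(path, mode: str, net1: PPINetwork, net2: PPINetwork) -> SeqSimTable:
    """Read a BLAST-tabular-like table (id1 id2 bitscore evalue).

    ``mode`` selects the raw score: ``"bitscore"`` uses the bit-score
    column, ``"neglog_evalue"`` uses -log10 of the e-value (clamped).
    Pairs whose identifiers are not in the respective networks are dropped
    with a logged count.
    """
    if mode not in ("bitscore", "neglog_evalue"):
        raise ValueError(f"unknown seqsim mode {mode!r}")
    path = Path(path)
    v1, v2 = net1.node_set, net2.node_set
    scores: dict = {}
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(
                    f"{path}:{lineno}: expected >=4 columns (id1 id2 bitscore evalue)"
                )
            u, v = fields[0], fields[1]
            bitscore, evalue = float(fields[2]), float(fields[3])
            if bitscore < 0:
                raise ParseError(f"{path}:{lineno}: negative bit-score {bitscore}")
            if u not in v1 or v not in v2:
                n_dropped += 1
                continue
            raw = bitscore if mode == "bitscore" else evalue_to_raw(evalue)
            # keep the best score for duplicated pairs (multiple HSPs)
            if raw > scores.get((u, v), -1.0):
                scores[(u, v)] = raw
    if n_dropped:
        logger.info("%s: dropped %d pair(s) with ids outside the networks", path, n_dropped)
    return SeqSimTable(scores=scores, mode=mode)


# ---------------------------------------------------------------------------
# Matchings
# ---------------------------------------------------------------------------


def write_matching(matching, path) -> None:
    """Write a matching as two-column TSV, sorted by the V1 identifier."""
    with open(path, "w") as fh:
        for u, v in sorted(matching.pairs):
            fh.write(f"{u}\t{v}\n")


def read_matching(path):
    """Read a two-column TSV node mapping into a :class:`~gmalign.construct.Matching`."""
    from .construct import Matching

    path = Path(path)
    m = Matching()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            m.add(fields[0], fields[1])
    return m


# ---------------------------------------------------------------------------
# GO annotations and ontology
# ---------------------------------------------------------------------------


@dataclass
class AnnotationSet:
    """Per-category (BP/MF/CC) map protein -> set of GO term identifiers."""

    by_category: dict = field(
        default_factory=lambda: {c: {} for c in CATEGORIES}
    )

    def add(self, protein: str, category: str, term: str) -> None:
        if category not in CATEGORIES:
            raise ValueError(f"unknown GO category {category!r}")
        self.by_category[category].setdefault(protein, set()).add(term)

    def terms(self, protein: str, category: str | None = None) -> set:
        """Terms of a protein; pooled across categories when ``category`` is None."""
        if category is not None:
            return set(self.by_category[category].get(protein, ()))
        out: set = set()
        for c in CATEGORIES:
            out |= self.by_category[c].get(protein, set())
        return out

    def annotated(self, category: str | None = None) -> set:
        """Proteins with at least one term (in the category, or any)."""
        if category is not None:
            return {p for p, ts in self.by_category[category].items() if ts}
        out: set = set()
        for c in CATEGORIES:
            out |= {p for p, ts in self.by_category[c].items() if ts}
        return out


def read_annotations(
    path,
    include_evidence=None,
    exclude_evidence=None,
) -> AnnotationSet:
    """Read a TSV annotation table: protein, category, term[, evidence].

    Evidence-code filtering (e.g. removing IPI annotations inferred from the
    PPIs themselves) is honoured through the optional fourth column and the
    ``include_evidence`` / ``exclude_evidence`` collections.
    """
    path = Path(path)
    include = set(include_evidence) if include_evidence else None
    exclude = set(exclude_evidence) if exclude_evidence else set()
    ann = AnnotationSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) not in (3, 4):
                raise ParseError(f"{path}:{lineno}: expected 3 or 4 columns")
            protein, category, term = fields[:3]
            if category not in CATEGORIES:
                raise ParseError(
                    f"{path}:{lineno}: unknown category {category!r} "
                    f"(expected one of {CATEGORIES})"
                )
            if len(fields) == 4:
                evidence = fields[3]
                if include is not None and evidence not in include:
                    continue
                if evidence in exclude:
                    continue
            ann.add(protein, category, term)
    return ann


@dataclass
class OntologyDAG:
    """is_a hierarchy over GO terms, acyclic, with per-category roots."""

    parents: dict = field(default_factory=dict)  # term -> set of parents
    namespace: dict = field(default_factory=dict)  # term -> BP/MF/CC

    @property
    def terms(self) -> set:
        return set(self.parents)

    @property
    def roots(self) -> set:
        return {t for t, ps in self.parents.items() if not ps}

    def ancestors(self, term: str) -> set:
        """All is_a ancestors of ``term``, including the term itself."""
        seen = {term}
        stack = [term]
        while stack:
            t = stack.pop()
            for p in self.parents.get(t, ()):
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        return seen

    def descendants_index(self) -> dict:
        """Map term -> set of descendants (including self)."""
        out: dict = {t: {t} for t in self.parents}
        for t in self.parents:
            for a in self.ancestors(t):
                out.setdefault(a, {a}).add(t)
        return out


def read_ontology(path) -> OntologyDAG:
    """Parse an OBO file (``[Term]``, ``id``, ``is_a``, ``namespace``).

    Raises :class:`ParseError` if the is_a relation is cyclic.
    """
    graph = obonet.read_obo(str(path))
    parents: dict = {}
    namespace: dict = {}
    isa = nx.DiGraph()
    for term, data in graph.nodes(data=True):
        parents.setdefault(term, set())
        isa.add_node(term)
        ns = data.get("namespace")
        if ns in _NAMESPACE_TO_CATEGORY:
            namespace[term] = _NAMESPACE_TO_CATEGORY[ns]
    for child, parent, key in graph.edges(keys=True):
        if key != "is_a":
            continue
        parents.setdefault(child, set()).add(parent)
        parents.setdefault(parent, set())
        isa.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(isa):
        raise ParseError(f"{path}: cyclic is_a hierarchy")
    return OntologyDAG(parents=parents, namespace=namespace)
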