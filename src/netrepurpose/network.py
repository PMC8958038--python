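"""Graph substrate for network-based drug repurposing.

This module owns the shared machinery every scorer relies on: the
:class:`GeneNetwork` container (an undirected simple graph of gene/protein
identifiers), edge-list ingestion with confidence thresholding, multi-source
hop distances, crosstalk counting between node sets, degree binning,
degree-matched node sampling and topology-preserving link shuffling.

Edges are treated as unweighted everywhere after thresholding: the
confidence column only decides which edges enter the graph (and is retained
for reporting); all path and crosstalk computation is purely topological.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import dijkstra

logger = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "DegreeBins",
    "NetworkError",
    "NetworkParseError",
    "EmptyNetworkError",
    "load_network",
    "shortest_path_from_set",
    "crosstalk_count",
    "max_crosstalk",
    "build_degree_bins",
    "sample_degree_matched",
    "shuffle_preserving_degree",
]


class NetworkError(ValueError):
    """Base class for errors raised by the network layer."""


class NetworkParseError(NetworkError):
    """A malformed row was encountered while reading an edge list."""


class EmptyNetworkError(NetworkError):
    """No edges survived thresholding/filtering."""


class GeneNetwork:
    """Undirected simple graph of gene/protein nodes.

    Wraps a :class:`networkx.Graph` and lazily caches the derived
    structures the scorers need repeatedly: an adjacency dict of sets, a
    deterministic node ordering, and a CSR adjacency matrix for fast
    multi-source breadth-first distances.

    Invariants: no self-loops, each unordered node pair appears at most
    once, and every edge endpoint is a node of the graph (all guaranteed by
    the networkx container plus the self-loop check at construction).
    """

    def __init__(self, graph: nx.Graph):
        n_loops = nx.number_of_selfloops(graph)
        if n_loops:
            raise NetworkError(f"graph contains {n_loops} self-loop(s)")
        self._g = graph
        self._adj: dict | None = None
        self._nodelist: list | None = None
        self._index: dict | None = None
        self._csr = None

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        confidence: Mapping[tuple, float] | None = None,
        nodes: Iterable | None = None,
    ) -> "GeneNetwork":
        """Build a network from an iterable of (u, v) pairs.

        ``confidence`` maps (u, v) pairs (either orientation) to a value in
        [0, 1] stored as an edge attribute. ``nodes`` may add isolated
        nodes beyond the edge endpoints.
        """
        g = nx.Graph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        for u, v in edges:
            g.add_edge(u, v)
        if confidence:
            for (u, v), c in confidence.items():
                if g.has_edge(u, v):
                    g[u][v]["confidence"] = float(c)
        return cls(g)

    # -- container surface -------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    @property
    def node_set(self) -> frozenset:
        return frozenset(self._g.nodes)

    def __contains__(self, node) -> bool:
        return node in self._g

    def degree(self, node) -> int:
        return self._g.degree[node]

    def edges(self):
        return self._g.edges()

    def adjacency(self) -> dict:
        """node -> set of neighbours (cached)."""
        if self._adj is None:
            self._adj = {u: set(nbrs) for u, nbrs in self._g.adjacency()}
        return self._adj

    @property
    def nodelist(self) -> list:
        """Deterministic (sorted) node ordering used for array indexing."""
        if self._nodelist is None:
            self._nodelist = sorted(self._g.nodes, key=str)
        return self._nodelist

    @property
    def node_index(self) -> dict:
        if self._index is None:
            self._index = {n: i for i, n in enumerate(self.nodelist)}
        return self._index

    def _adjacency_csr(self):
        if self._csr is None:
            self._csr = nx.to_scipy_sparse_array(
                self._g, nodelist=self.nodelist, weight=None, format="csr"
            )
        return self._csr

    # -- distances ---------------------------------------------------------

    def hop_distance_array(self, sources: Iterable) -> np.ndarray:
        """Hop count from the nearest source to every node.

        Returns a float array aligned with :attr:`nodelist`; unreachable
        nodes are ``inf``. Computed in C via scipy's unweighted
        multi-source shortest path (equivalent to BFS from a super-source).
        """
        idx = [self.node_index[s] for s in sources]
        if not idx:
            raise NetworkError("empty source set for shortest-path query")
        return dijkstra(
            self._adjacency_csr(),
            directed=False,
            indices=idx,
            unweighted=True,
            min_only=True,
        )

    def largest_component(self) -> "GeneNetwork":
        comp = max(nx.connected_components(self._g), key=len)
        return GeneNetwork(self._g.subgraph(comp).copy())


# ---------------------------------------------------------------------------
# ingestion


def _parse_edge_rows(path):
    """Yield (line_no, u, v, confidence-or-None) from a TSV edge list."""
    first_data_seen = False
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or len(fields) > 3 or not fields[0] or not fields[1]:
                raise NetworkParseError(
                    f"{path}: line {line_no}: expected 2-3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            conf = None
            if len(fields) == 3:
                try:
                    conf = float(fields[2])
                except ValueError:
                    if not first_data_seen:
                        # header line detected by non-numeric third field
                        continue
                    raise NetworkParseError(
                        f"{path}: line {line_no}: non-numeric confidence "
                        f"{fields[2]!r}"
                    )
            first_data_seen = True
            yield line_no, fields[0], fields[1], conf


def load_network(
    edge_table_path,
    confidence_threshold: float = 0.8,
    keep_largest_component: bool = False,
) -> GeneNetwork:
    """Read a tab-separated edge list into a :class:`GeneNetwork`.

    Columns are (nodeA, nodeB[, confidence]); '#'-prefixed comment lines and
    an optional header (detected by a non-numeric third field) are skipped.
    Only edges with confidence >= ``confidence_threshold`` are kept (rows
    without a confidence column always pass). Self-loop rows are dropped
    with a logged count; duplicate and reversed-duplicate rows collapse to
    one edge keeping the maximum confidence.
    """
    if not 0.0 <= confidence_threshold <= 1.0:
        raise ValueError("confidence_threshold must lie in [0, 1]")
    edges: dict[frozenset, float | None] = {}
    n_self = 0
    n_below = 0
    for line_no, u, v, conf in _parse_edge_rows(edge_table_path):
        if u == v:
            n_self += 1
            continue
        if conf is not None and conf < confidence_threshold:
            n_below += 1
            continue
        key = frozenset((u, v))
        prev = edges.get(key, None)
        if key not in edges or (
            conf is not None and (prev is None or conf > prev)
        ):
            edges[key] = conf
    if n_self:
        logger.info("load_network: dropped %d self-loop row(s)", n_self)
    if n_below:
        logger.info(
            "load_network: dropped %d edge(s) below confidence %.3g",
            n_below,
            confidence_threshold,
        )
    if not edges:
        raise EmptyNetworkError(
            f"{edge_table_path}: no edges remain at confidence threshold "
            f"{confidence_threshold}"
        )
    g = nx.Graph()
    for key, conf in edges.items():
        u, v = sorted(key, key=str)
        if conf is None:
            g.add_edge(u, v)
        else:
            g.add_edge(u, v, confidence=conf)
    net = GeneNetwork(g)
    if keep_largest_component:
        net = net.largest_component()
    return net


# ---------------------------------------------------------------------------
# distances and crosstalk


def shortest_path_from_set(net: GeneNetwork, sources: Iterable) -> dict:
    """Hop distance from the nearest source for every reachable node.

    Unreachable nodes are absent from the mapping (not infinite); source
    nodes map to 0.
    """
    sources = set(sources)
    if not sources:
        raise NetworkError("empty source set")
    missing = sources - net.node_set
    if missing:
        raise NetworkError(f"source node(s) not in network: {sorted(missing, key=str)[:5]}")
    dist = net.hop_distance_array(sources)
    nodes = net.nodelist
    return {nodes[i]: int(d) for i, d in enumerate(dist) if np.isfinite(d)}


def crosstalk_count(net: GeneNetwork, set_a: Iterable, set_b: Iterable) -> int:
    """Number of distinct network edges with one endpoint in each set.

    Sets may overlap; an edge with both endpoints in the intersection is
    counted once (the convention that keeps the count symmetric and bounded
    by :func:`max_crosstalk`).
    """
    a = set(set_a)
    b = set(set_b)
    if not a or not b:
        return 0
    bad = (a | b) - net.node_set
    if bad:
        raise NetworkError(f"set member(s) not in network: {sorted(bad, key=str)[:5]}")
    adj = net.adjacency()
    # sum over a of |N(a) ∩ B| counts edges inside A∩B twice
    total = sum(len(adj[u] & b) for u in a)
    both = a & b
    if both:
        internal = sum(len(adj[u] & both) for u in both) // 2
        total -= internal
    return total


def max_crosstalk(set_a: Iterable, set_b: Iterable) -> int:
    """Number of unordered node pairs eligible to be crosstalk edges.

    |A|·|B| − o − o·(o−1)/2 with o = |A ∩ B|: pairs within the overlap are
    counted once and self-pairs never qualify.
    """
    a = set(set_a)
    b = set(set_b)
    o = len(a & b)
    return len(a) * len(b) - o - o * (o - 1) // 2


# ---------------------------------------------------------------------------
# degree binning and degree-matched sampling


@dataclass(frozen=True)
class DegreeBins:
    """Degree-contiguous node bins for degree-aware sampling.

    Nodes are sorted by (degree, identifier) and chunked into consecutive
    bins of ``bin_size``; a final remainder bin smaller than bin_size/2 is
    merged into the preceding bin. ``bins`` keeps the sorted order, so
    sampling from a bin is deterministic given a seeded generator.
    """

    bin_size: int
    bins: tuple[tuple, ...]
    assignment: Mapping = field(repr=False)

    def counts_for(self, node_set: Iterable) -> dict[int, int]:
        """Per-bin multiplicity of a node set."""
        out: dict[int, int] = {}
        for n in node_set:
            b = self.assignment[n]
            out[b] = out.get(b, 0) + 1
        return out


def build_degree_bins(net: GeneNetwork, bin_size: int = 100) -> DegreeBins:
    """Partition nodes into degree-contiguous bins of ``bin_size``.

    Ties in degree are broken lexicographically so the binning is
    deterministic. If ``bin_size`` exceeds the node count a single bin is
    returned with a warning.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    ordered = sorted(net.graph.nodes, key=lambda n: (net.degree(n), str(n)))
    n = len(ordered)
    if bin_size > n:
        logger.warning(
            "build_degree_bins: bin_size %d exceeds node count %d; using one bin",
            bin_size,
            n,
        )
        bins = [ordered]
    else:
        bins = [ordered[i : i + bin_size] for i in range(0, n, bin_size)]
        if len(bins) > 1 and len(bins[-1]) < bin_size / 2:
            tail = bins.pop()
            bins[-1] = bins[-1] + tail
    assignment = {node: i for i, chunk in enumerate(bins) for node in chunk}
    return DegreeBins(
        bin_size=bin_size,
        bins=tuple(tuple(chunk) for chunk in bins),
        assignment=assignment,
    )


def sample_degree_matched(
    net: GeneNetwork,
    bins: DegreeBins,
    reference_set: Iterable,
    rng: np.random.Generator,
) -> set:
    """Random node set matching the reference set's size and bin profile.

    For every degree bin, as many nodes are drawn (uniformly, without
    replacement) as the reference set contributes to that bin, so the
    sample reproduces the reference degree distribution at bin resolution.
    """
    reference_set = set(reference_set)
    missing = reference_set - net.node_set
    if missing:
        raise NetworkError(f"reference node(s) not in network: {sorted(missing, key=str)[:5]}")
    out: list = []
    for b, count in sorted(bins.counts_for(reference_set).items()):
        pool = bins.bins[b]
        if count > len(pool):
            raise NetworkError(
                f"bin {b} holds {len(pool)} nodes but {count} were requested"
            )
        chosen = rng.choice(len(pool), size=count, replace=False)
        out.extend(pool[i] for i in chosen)
    return set(out)


# ---------------------------------------------------------------------------
# topology-preserving randomization


def shuffle_preserving_degree(
    net: GeneNetwork,
    swap_factor: float = 10.0,
    rng: np.random.Generator | None = None,
) -> GeneNetwork:
    """Degree-preserving link shuffle via attempted double-edge swaps.

    Performs ceil(swap_factor × |E|) swap attempts: two edges {a,b},{c,d}
    are rewired to {a,d},{c,b} iff the result introduces no self-loop and
    no duplicate edge; failed attempts are skipped and counted. The
    returned graph has the exact degree sequence of the input.
    """
    if rng is None:
        raise ValueError("an explicit seeded numpy Generator is required")
    if net.n_edges < 2:
        raise NetworkError("need at least 2 edges to shuffle")
    edges = [tuple(sorted(e, key=str)) for e in net.graph.edges()]
    edges.sort(key=lambda e: (str(e[0]), str(e[1])))
    edge_set = set(edges)
    m = len(edges)
    n_attempts = math.ceil(swap_factor * m)
    pairs = rng.integers(0, m, size=(n_attempts, 2))
    flips = rng.random(n_attempts) < 0.5
    n_failed = 0
    for (i, j), flip in zip(pairs, flips):
        if i == j:
            n_failed += 1
            continue
        a, b = edges[i]
        c, d = edges[j]
        if flip:
            c, d = d, c
        # candidate rewiring: {a,d}, {c,b}
        if a == d or c == b:
            n_failed += 1
            continue
        e1 = (a, d) if str(a) <= str(d) else (d, a)
        e2 = (c, b) if str(c) <= str(b) else (b, c)
        if e1 in edge_set or e2 in edge_set:
            n_failed += 1
            continue
        edge_set.discard(edges[i])
        edge_set.discard(edges[j])
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = e1
        edges[j] = e2
    logger.debug(
        "shuffle_preserving_degree: %d/%d attempts failed", n_failed, n_attempts
    )
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    g.add_edges_from(edge_set)
    return GeneNetwork(g)
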