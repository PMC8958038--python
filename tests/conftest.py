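"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (edge scans, all-pairs
enumeration, O(n^2) step-up) so they stay independent of the code paths
they check.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from netrepurpose.network import GeneNetwork


@pytest.fixture
def path5() -> GeneNetwork:
    """Path graph 1-2-3-4-5 (string node ids)."""
    return GeneNetwork.from_edges([("1", "2"), ("2", "3"), ("3", "4"), ("4", "5")])


@pytest.fixture(scope="session")
def ba300() -> GeneNetwork:
    """Small preferential-attachment graph for stochastic unit tests."""
    g = nx.barabasi_albert_graph(300, 3, seed=1)
    return GeneNetwork(nx.relabel_nodes(g, {i: f"g{i:03d}" for i in g.nodes}))


def random_instance(seed: int, max_n: int = 50):
    """Random (network, setA, setB) with possibly overlapping sets."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, max_n + 1))
    p = float(rng.uniform(0.05, 0.4))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
    nodes = sorted(g.nodes)
    ka = int(rng.integers(1, max(2, n // 2)))
    kb = int(rng.integers(1, max(2, n // 2)))
    set_a = set(rng.choice(nodes, size=ka, replace=False).tolist())
    set_b = set(rng.choice(nodes, size=kb, replace=False).tolist())
    return GeneNetwork(g), set_a, set_b


# ---------------------------------------------------------------------------
# oracles


def brute_crosstalk(net: GeneNetwork, set_a: set, set_b: set) -> int:
    """Edge scan: distinct edges with one endpoint in each set."""
    count = 0
    for u, v in net.graph.edges():
        if (u in set_a and v in set_b) or (u in set_b and v in set_a):
            count += 1
    return count


def brute_max_crosstalk(set_a: set, set_b: set) -> int:
    """Enumeration of all unordered node pairs eligible as crosstalk edges."""
    pairs = set()
    for a in set_a:
        for b in set_b:
            if a != b:
                pairs.add(frozenset((a, b)))
    return len(pairs)


def brute_min_distance_from_set(net: GeneNetwork, sources: set) -> dict:
    """Min over per-source BFS distances (networkx as independent engine)."""
    out: dict = {}
    for s in sources:
        for node, d in nx.single_source_shortest_path_length(net.graph, s).items():
            if node not in out or d < out[node]:
                out[node] = d
    return out


def brute_auroc(scores, labels) -> float:
    """All-pairs positive-vs-negative comparison with ties scoring 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (pos.size * neg.size)


def brute_aupr(scores, labels) -> float:
    """Step-wise area: sum (R_k - R_{k-1}) * P_k over distinct thresholds."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = labels.sum()
    area = 0.0
    prev_recall = 0.0
    for t in sorted(set(scores.tolist()), reverse=True):
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        precision = tp / pred.sum()
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def brute_bh(pvalues) -> np.ndarray:
    """Direct step-up definition: q_(i) = min_{k>=i} m*p_(k)/(k+1), clipped."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    sorted_p = p[order]
    for i in range(m):
        q[order[i]] = min(
            min(m * sorted_p[k] / (k + 1) for k in range(i, m)), 1.0
        )
    return q


def brute_hypergeom_moments(n_nodes: int, k: int, n: int):
    """Hypergeometric mean/sd via scipy's distribution (independent route)."""
    from scipy.stats import hypergeom

    dist = hypergeom(M=n_nodes, n=k, N=n)
    return float(dist.mean()), float(dist.std())
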