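"""Synthetic networks, gene sets and benchmarks with planted signal.

Emulates the shape of the real inputs — a heavy-tailed functional
association network, diseases with at least 20 genes forming connected
modules, drugs with few targets (median 3) — and plants a controllable
drug–disease association signal so that the whole pipeline is testable
without any external database:

* the network is a preferential-attachment (Barabási–Albert) graph, whose
  degree heterogeneity is precisely what the degree-aware nulls exist to
  handle;
* each disease is a connected neighborhood-grown node set (disease
  modules are locally coherent in functional networks);
* a fraction of drugs receive one indicated disease ("approved"); for
  those pairs a ``signal_rewire_prob`` fraction of each target's edges is
  rewired onto uniformly chosen disease genes (raising crosstalk and
  shortening paths while preserving the target's degree), and target–gene
  overlap is planted at a class-conditional rate;
* all remaining combinations are labeled "unknown".
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import io as nrio
from .network import GeneNetwork

logger = logging.getLogger(__name__)

__all__ = ["SyntheticConfig", "SyntheticBenchmark", "generate_network", "plant_disease", "generate_benchmark"]


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic benchmark.

    Defaults describe a desk-scale analogue of the real data: 2,000 genes,
    mean degree ~6, 5 diseases of 20–60 genes, 30 drugs with 1–5 targets
    (median 3), half the drugs carrying one approved indication, half of
    each positive target's links rewired onto its disease, and target–gene
    overlap planted at 0.3 (positives) vs 0.02 (negatives).
    """

    n_nodes: int = 2000
    attachment_edges: int = 3
    n_diseases: int = 5
    disease_size_range: tuple[int, int] = (20, 60)
    n_drugs: int = 30
    targets_per_drug_range: tuple[int, int] = (1, 5)
    positive_fraction: float = 0.5
    signal_rewire_prob: float = 0.5
    overlap_prob_positive: float = 0.3
    overlap_prob_negative: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.disease_size_range[0] < 1:
            raise SyntheticError("disease_size_range min must be >= 1")
        if self.n_nodes <= self.disease_size_range[1]:
            raise SyntheticError("n_nodes must exceed the largest disease size")
        for p in (
            self.positive_fraction,
            self.signal_rewire_prob,
            self.overlap_prob_positive,
            self.overlap_prob_negative,
        ):
            if not 0.0 <= p <= 1.0:
                raise SyntheticError("probabilities must lie in [0, 1]")


@dataclass
class SyntheticBenchmark:
    """Generated inputs plus the planted ground truth."""

    network: GeneNetwork
    drug_sets: dict[str, set]
    disease_sets: dict[str, set]
    labels: pd.DataFrame  # (drug_id, disease_id, label)
    truth: pd.DataFrame  # (drug_id, disease_id, planted: bool)
    config: SyntheticConfig

    def write(self, out_dir) -> None:
        """Write network.tsv, drugs.gmt, diseases.gmt, labels.tsv, truth.tsv, config.yaml."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        nrio.write_network_tsv(self.network, out / "network.tsv")
        nrio.write_gmt(self.drug_sets, out / "drugs.gmt")
        nrio.write_gmt(self.disease_sets, out / "diseases.gmt")
        nrio.write_label_table(self.labels, out / "labels.tsv")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        cfg = asdict(self.config)
        cfg["disease_size_range"] = list(cfg["disease_size_range"])
        cfg["targets_per_drug_range"] = list(cfg["targets_per_drug_range"])
        with open(out / "config.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)


def _node_name(i: int, width: int) -> str:
    return f"g{i:0{width}d}"


def generate_network(config: SyntheticConfig, rng: np.random.Generator) -> GeneNetwork:
    """Connected preferential-attachment graph with heavy-tailed degrees."""
    n, m = config.n_nodes, config.attachment_edges
    if n < 10:
        raise SyntheticError("n_nodes must be >= 10")
    if m < 1 or m >= n:
        raise SyntheticError("attachment_edges must lie in [1, n_nodes)")
    seed = int(rng.integers(0, 2**31 - 1))
    g_int = nx.barabasi_albert_graph(n, m, seed=seed)
    width = len(str(n - 1))
    mapping = {i: _node_name(i, width) for i in g_int.nodes}
    return GeneNetwork(nx.relabel_nodes(g_int, mapping))


def plant_disease(
    net: GeneNetwork, size: int, rng: np.random.Generator, max_restarts: int = 50
) -> set:
    """Connected neighborhood-grown node set of the requested size.

    Starting from a random seed node, repeatedly adds a uniformly chosen
    neighbor of the current set; restarts from a fresh seed node (bounded)
    if growth stalls in a small component.
    """
    if size > net.n_nodes:
        raise SyntheticError("disease size exceeds the network")
    adj = net.adjacency()
    nodes = net.nodelist
    for _ in range(max_restarts):
        start = nodes[rng.integers(0, len(nodes))]
        members = {start}
        frontier = set(adj[start])
        while len(members) < size and frontier:
            pick = sorted(frontier)[rng.integers(0, len(frontier))]
            members.add(pick)
            frontier |= adj[pick]
            frontier -= members
        if len(members) == size:
            return members
    raise SyntheticError(f"could not grow a connected set of size {size}")


def _rewire_onto_disease(
    g: nx.Graph, target, disease_genes: list, p: float, rng: np.random.Generator
) -> int:
    """Rewire each (target, u) edge onto a random disease gene with prob p.

    Degree-preserving for the target node; skips rewirings that would
    create a self-loop or duplicate edge. Returns the number rewired.
    """
    n_done = 0
    for u in list(g.neighbors(target)):
        if rng.random() >= p:
            continue
        gene = disease_genes[rng.integers(0, len(disease_genes))]
        if gene == target or g.has_edge(target, gene):
            continue
        g.remove_edge(target, u)
        g.add_edge(target, gene)
        n_done += 1
    return n_done


def generate_benchmark(config: SyntheticConfig) -> SyntheticBenchmark:
    """Generate network, gene sets, labels and truth with planted signal.

    Positive (drug, disease) pairs are labeled "approved" and receive the
    planted signal (edge rewiring plus overlap); all other combinations are
    labeled "unknown". The truth table flags exactly the planted pairs.
    """
    rng = np.random.default_rng(config.seed)
    net = generate_network(config, rng)
    g = net.graph.copy()
    nodes = net.nodelist

    lo, hi = config.disease_size_range
    disease_sets: dict[str, set] = {}
    for i in range(config.n_diseases):
        size = int(rng.integers(lo, hi + 1))
        disease_sets[f"D{i:02d}"] = plant_disease(net, size, rng)

    disease_ids = list(disease_sets)
    n_pos_drugs = int(round(config.positive_fraction * config.n_drugs))
    pos_drug_idx = set(rng.choice(config.n_drugs, size=n_pos_drugs, replace=False).tolist())

    t_lo, t_hi = config.targets_per_drug_range
    drug_sets: dict[str, set] = {}
    positive_pairs: list[tuple[str, str]] = []
    for j in range(config.n_drugs):
        drug = f"DR{j:03d}"
        k = int(rng.integers(t_lo, t_hi + 1))
        targets = set(rng.choice(nodes, size=k, replace=False).tolist())
        if j in pos_drug_idx:
            disease = disease_ids[int(rng.integers(0, len(disease_ids)))]
            genes = sorted(disease_sets[disease])
            if rng.random() < config.overlap_prob_positive:
                # plant overlap: swap one target for a disease gene
                t_out = sorted(targets)[rng.integers(0, len(targets))]
                t_in = genes[rng.integers(0, len(genes))]
                targets = (targets - {t_out}) | {t_in}
            positive_pairs.append((drug, disease))
        else:
            if rng.random() < config.overlap_prob_negative:
                disease = disease_ids[int(rng.integers(0, len(disease_ids)))]
                genes = sorted(disease_sets[disease])
                t_out = sorted(targets)[rng.integers(0, len(targets))]
                t_in = genes[rng.integers(0, len(genes))]
                targets = (targets - {t_out}) | {t_in}
        drug_sets[drug] = targets

    # plant the association signal by degree-preserving rewiring
    for drug, disease in positive_pairs:
        genes = sorted(disease_sets[disease])
        for t in sorted(drug_sets[drug]):
            _rewire_onto_disease(g, t, genes, config.signal_rewire_prob, rng)

    planted = set(positive_pairs)
    label_rows = []
    truth_rows = []
    for disease in disease_ids:
        for drug in drug_sets:
            is_pos = (drug, disease) in planted
            label_rows.append(
                {
                    "drug_id": drug,
                    "disease_id": disease,
                    "label": "approved" if is_pos else "unknown",
                }
            )
            truth_rows.append(
                {"drug_id": drug, "disease_id": disease, "planted": is_pos}
            )
    labels = pd.DataFrame(label_rows)
    truth = pd.DataFrame(truth_rows)
    logger.info(
        "generate_benchmark: %d drugs x %d diseases, %d planted positives",
        config.n_drugs,
        config.n_diseases,
        len(planted),
    )
    return SyntheticBenchmark(
        network=GeneNetwork(g),
        drug_sets=drug_sets,
        disease_sets=disease_sets,
        labels=labels,
        truth=truth,
        config=config,
    )
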