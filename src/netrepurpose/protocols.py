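"""Reference experimental protocols for validating the scoring platform.

These functions bundle the standard experiments used to qualify the
package on synthetic data — null-model calibration, the planted-signal
benchmark pipeline, and the drug–drug similarity comparison — so that the
test suite and reproduction scripts run exactly the same procedures.

All randomness flows from explicit integer seeds through
``numpy.random.SeedSequence`` spawning, so every experiment is exactly
reproducible and different sub-experiments get independent streams.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .evaluation import balanced_auroc, negative_draws
from .network import GeneNetwork, build_degree_bins
from .scoring import METHODS, score_all_pairs, similarity_table
from .synthetic import SyntheticConfig, generate_benchmark

logger = logging.getLogger(__name__)

__all__ = [
    "calibration_zscores",
    "calibration_summary",
    "score_benchmark",
    "oriented_scores_and_truth",
    "balanced_aurocs_by_method",
    "run_planted_pipeline",
    "run_similarity_comparison",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


# ---------------------------------------------------------------------------
# null calibration


def calibration_zscores(
    seed: int,
    methods: Sequence[str] = METHODS,
    n_nodes: int = 2000,
    attachment_edges: int = 3,
    n_batches: int = 8,
    sets_per_batch: int = 25,
    disease_size: int = 40,
    target_size: int = 5,
    n_perm: int = 1000,
    n_samples: int = 100,
    n_random_networks: int = 100,
) -> dict[str, np.ndarray]:
    """z-scores of null (random) target sets under each method.

    On one preferential-attachment network, ``n_batches`` fixed disease
    sets are drawn uniformly; against each, ``sets_per_batch`` uniformly
    random target sets are scored. For a calibrated null the pooled z
    should have mean ~0 and a ~5% |z| > 1.96 tail. Batching over several
    disease sets averages out the disease-set draw, which otherwise
    dominates the spread of the pooled mean.
    """
    net_seed, set_seed, score_seed = _child_seeds(seed, 3)
    g = nx.barabasi_albert_graph(n_nodes, attachment_edges, seed=net_seed)
    net = GeneNetwork(nx.relabel_nodes(g, {i: f"g{i:05d}" for i in g.nodes}))
    nodes = net.nodelist
    rng = np.random.default_rng(set_seed)
    diseases: dict[str, set] = {}
    drugs: dict[str, set] = {}
    pairs: set = set()
    for b in range(n_batches):
        did = f"S{b:02d}"
        diseases[did] = set(rng.choice(nodes, disease_size, replace=False).tolist())
        for j in range(sets_per_batch):
            drug = f"T{b:02d}_{j:03d}"
            drugs[drug] = set(rng.choice(nodes, target_size, replace=False).tolist())
            pairs.add((drug, did))
    bins = build_degree_bins(net)
    out = {}
    for method, child in zip(methods, _child_seeds(score_seed, len(methods))):
        tab = score_all_pairs(
            net,
            drugs,
            diseases,
            method,
            rng=np.random.default_rng(child),
            n_perm=n_perm,
            n_samples=n_samples,
            n_random_networks=n_random_networks,
            bins=bins,
            pairs=pairs,
        )
        z = tab["z"].to_numpy()
        out[method] = z[np.isfinite(z)]
    return out


def calibration_summary(seed: int, **kwargs) -> dict[str, dict[str, float]]:
    """Mean z and |z|>1.96 tail rate per method for the calibration run."""
    return {
        method: {
            "mean_z": float(z.mean()),
            "tail_rate": float((np.abs(z) > 1.96).mean()),
            "n": int(z.size),
        }
        for method, z in calibration_zscores(seed, **kwargs).items()
    }


# ---------------------------------------------------------------------------
# planted-signal pipeline


def score_benchmark(
    bench,
    seed: int,
    methods: Sequence[str] = METHODS,
    n_perm: int = 1000,
    n_samples: int = 100,
    n_random_networks: int = 100,
) -> dict[str, pd.DataFrame]:
    """Score every pair of a synthetic benchmark with each method."""
    bins = build_degree_bins(bench.network)
    tables = {}
    for method, child in zip(methods, _child_seeds(seed, len(methods))):
        tables[method] = score_all_pairs(
            bench.network,
            bench.drug_sets,
            bench.disease_sets,
            method,
            rng=np.random.default_rng(child),
            n_perm=n_perm,
            n_samples=n_samples,
            n_random_networks=n_random_networks,
            bins=bins,
        )
    return tables


def oriented_scores_and_truth(table: pd.DataFrame, truth: pd.DataFrame):
    """(oriented score, planted label) arrays for finite-score pairs."""
    t = truth.set_index(["drug_id", "disease_id"])["planted"]
    sign = np.where(table["direction"] == "lower_is_stronger", -1.0, 1.0)
    s = (sign * table["z"]).to_numpy()
    l = t.loc[list(zip(table["drug_id"], table["disease_id"]))].to_numpy().astype(int)
    ok = np.isfinite(s)
    return s[ok], l[ok]


def balanced_aurocs_by_method(
    scored: Mapping[str, tuple[np.ndarray, np.ndarray]],
    seed: int,
    n_resamples: int = 100,
) -> dict[str, list[float]]:
    """Balanced-sample AUROC vectors with shared negative draws (paired design).

    ``scored`` maps method -> (oriented scores, labels). The same negative
    index draws are reused for every method whose pair universe matches
    the first one's, so method comparisons are paired.
    """
    rng = np.random.default_rng(seed)
    draws = None
    shape = None
    out = {}
    for method, (s, l) in scored.items():
        n_pos, n_neg = int(l.sum()), int((1 - l).sum())
        if draws is None or (n_pos, n_neg) != shape:
            draws = negative_draws(n_neg, n_pos, n_resamples, rng)
            shape = (n_pos, n_neg)
        out[method] = balanced_auroc(s, l, draws=draws)
    return out


def run_planted_pipeline(
    generator_seed: int,
    score_seed: int,
    eval_seed: int,
    methods: Sequence[str] = METHODS,
    n_resamples: int = 100,
    **config_kwargs,
):
    """Simulate -> score all methods -> balanced AUROC per method.

    Returns (benchmark, score tables, {method: mean balanced AUROC}).
    """
    bench = generate_benchmark(SyntheticConfig(seed=generator_seed, **config_kwargs))
    tables = score_benchmark(bench, score_seed, methods=methods)
    scored = {
        m: oriented_scores_and_truth(tab, bench.truth) for m, tab in tables.items()
    }
    bal = balanced_aurocs_by_method(scored, eval_seed, n_resamples=n_resamples)
    aurocs = {m: float(np.mean(v)) for m, v in bal.items()}
    return bench, tables, aurocs


# ---------------------------------------------------------------------------
# drug–drug similarity comparison


def run_similarity_comparison(
    bench,
    association_aurocs: Mapping[str, float],
    seed: int,
    eval_seed: int,
    methods: Sequence[str] = ("proximity", "anubix"),
    n_resamples: int = 100,
) -> dict[str, dict[str, float]]:
    """Leave-one-out similarity AUROC vs association AUROC per method.

    References for each disease are the drugs labeled approved for it in
    the benchmark's label table.
    """
    approved = (
        bench.labels[bench.labels["label"].isin(("approved", "off_label"))]
        .groupby("disease_id")["drug_id"]
        .apply(list)
        .to_dict()
    )
    truth = bench.truth.set_index(["drug_id", "disease_id"])["planted"]
    out = {}
    for method, child in zip(methods, _child_seeds(seed, len(methods))):
        tab = similarity_table(
            bench.network,
            bench.drug_sets,
            approved,
            method,
            rng=np.random.default_rng(child),
        )
        s = tab["similarity"].to_numpy()
        l = (
            truth.loc[list(zip(tab["drug_id"], tab["disease_id"]))]
            .to_numpy()
            .astype(int)
        )
        ok = np.isfinite(s)
        bal = balanced_auroc(
            s[ok], l[ok], n_resamples=n_resamples, rng=np.random.default_rng(eval_seed)
        )
        out[method] = {
            "similarity_auroc": float(np.mean(bal)),
            "association_auroc": float(association_aurocs[method]),
        }
    return out
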