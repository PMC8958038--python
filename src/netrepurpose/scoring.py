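"""Drug–disease association scorers and drug–drug similarity.

Four scorers, each normalizing its raw statistic against a degree-aware
null model of the underlying functional association network:

* **proximity** — average shortest-path distance from each drug target to
  its closest disease gene, z-normalized against degree-matched random
  samples of both sets (lower distance = stronger association).
* **NEAT** — observed crosstalk (edge count between the two sets) against
  hypergeometric moments in node counts: mu_H = n*K/N with the matching
  hypergeometric standard deviation.
* **BinoX** — observed crosstalk against a binomial Bin(n_x, p_x) null
  whose p_x is estimated from degree-preserving link shuffles of the
  network.
* **ANUBIX** — observed crosstalk against a beta-binomial null fitted by
  maximum likelihood to crosstalk of degree-matched random target sets,
  capturing the over-dispersion the binomial misses.

All scorers emit an :class:`AssociationScore` with raw statistic, null
moments, z, and a direction-aware one-sided normal-tail p-value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .network import (
    DegreeBins,
    GeneNetwork,
    NetworkError,
    build_degree_bins,
    crosstalk_count,
    max_crosstalk,
    sample_degree_matched,
    shuffle_preserving_degree,
)

logger = logging.getLogger(__name__)

METHODS = ("proximity", "neat", "binox", "anubix")
Direction = Literal["lower_is_stronger", "higher_is_stronger"]

__all__ = [
    "METHODS",
    "AssociationScore",
    "BetaBinomialFit",
    "ScoringError",
    "DegenerateNullError",
    "proximity_distance",
    "proximity_score",
    "neat_score",
    "binox_score",
    "fit_betabinomial",
    "anubix_score",
    "oriented_score",
    "z_to_p",
    "drug_drug_similarity",
    "score_all_pairs",
    "similarity_table",
]


class ScoringError(ValueError):
    pass


class DegenerateNullError(ScoringError):
    """The null model has zero spread; no z-score can be formed."""


@dataclass
class AssociationScore:
    """One scored drug–disease (or drug–drug) pair."""

    method: str
    drug_id: str
    disease_id: str
    raw: float  # distance d for proximity, crosstalk x otherwise
    null_mean: float
    null_sd: float
    z: float
    p: float
    direction: Direction
    q: float = math.nan  # BH-adjusted, filled by the evaluation layer
    n_targets_used: int | None = None
    status: str = "ok"
    p_empirical: float | None = None  # permutation p (proximity only)

    def __post_init__(self):
        if self.null_sd > 0 and np.isfinite(self.z):
            assert abs(self.z - (self.raw - self.null_mean) / self.null_sd) < 1e-9


def oriented_score(score: AssociationScore) -> float:
    """z on a common 'higher = stronger association' scale."""
    return score.z if score.direction == "higher_is_stronger" else -score.z


def z_to_p(z: float, direction: Direction) -> float:
    """One-sided standard-normal tail p in the direction of association."""
    if direction == "lower_is_stronger":
        return float(stats.norm.cdf(z))
    return float(stats.norm.sf(z))


# ---------------------------------------------------------------------------
# proximity


def proximity_distance(net: GeneNetwork, targets: Iterable, disease_genes: Iterable) -> float:
    """d(T,S): mean over targets of the hop distance to the closest disease gene.

    Targets that cannot reach any disease gene are excluded from the mean
    (logged); if no target reaches any disease gene the distance is
    undefined and an error is raised.
    """
    targets = set(targets)
    disease_genes = set(disease_genes)
    if not targets or not disease_genes:
        raise ScoringError("proximity needs nonempty target and disease-gene sets")
    dist = net.hop_distance_array(disease_genes)
    idx = net.node_index
    vals = np.array([dist[idx[t]] for t in targets])
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ScoringError("no drug target can reach any disease gene")
    if finite.size < vals.size:
        logger.warning(
            "proximity_distance: %d/%d target(s) unreachable, excluded",
            vals.size - finite.size,
            vals.size,
        )
    return float(finite.mean())


def proximity_score(
    net: GeneNetwork,
    targets: Iterable,
    disease_genes: Iterable,
    bins: DegreeBins,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    drug_id: str = "drug",
    disease_id: str = "disease",
) -> AssociationScore:
    """Degree-aware permutation z-score for the proximity distance.

    Both the target-like and the disease-like set are resampled
    degree-matched in every permutation; z = (d_obs − mu_R)/sigma_R with a
    lower-tail normal p plus an empirical permutation p.
    """
    if rng is None:
        raise ValueError("an explicit seeded numpy Generator is required")
    targets = set(targets)
    disease_genes = set(disease_genes)
    d_obs = proximity_distance(net, targets, disease_genes)
    null = np.full(n_perm, np.nan)
    idx = net.node_index
    for i in range(n_perm):
        t_like = sample_degree_matched(net, bins, targets, rng)
        s_like = sample_degree_matched(net, bins, disease_genes, rng)
        dist = net.hop_distance_array(s_like)
        vals = np.array([dist[idx[t]] for t in t_like])
        finite = vals[np.isfinite(vals)]
        if finite.size:
            null[i] = finite.mean()
    null = null[np.isfinite(null)]
    if null.size == 0:
        raise ScoringError("all permutation distances undefined")
    mu, sd = float(null.mean()), float(null.std())
    if sd == 0:
        raise DegenerateNullError(
            f"proximity null has zero spread for ({drug_id}, {disease_id})"
        )
    z = (d_obs - mu) / sd
    return AssociationScore(
        method="proximity",
        drug_id=drug_id,
        disease_id=disease_id,
        raw=d_obs,
        null_mean=mu,
        null_sd=sd,
        z=z,
        p=z_to_p(z, "lower_is_stronger"),
        direction="lower_is_stronger",
        n_targets_used=len(targets),
        p_empirical=float((1 + (null <= d_obs).sum()) / (null.size + 1)),
    )


# ---------------------------------------------------------------------------
# NEAT


def neat_moments(n_nodes: int, k_targets: int, n_genes: int) -> tuple[float, float]:
    """Hypergeometric null moments in node counts: mu_H = n*K/N."""
    mu = n_genes * k_targets / n_nodes
    var = mu * (n_nodes - k_targets) / n_nodes * (n_nodes - n_genes) / (n_nodes - 1)
    return mu, math.sqrt(var)


def neat_score(
    net: GeneNetwork,
    targets: Iterable,
    disease_genes: Iterable,
    drug_id: str = "drug",
    disease_id: str = "disease",
) -> AssociationScore:
    """Analytic crosstalk z-score under the node-count hypergeometric null.

    No randomness: x is the observed crosstalk, mu_H = n*K/N and sigma_H
    the matching hypergeometric standard deviation. Note this null ignores
    node degrees; on heavy-tailed networks it understates the expected
    crosstalk, inflating z (a documented property of the method).
    """
    targets = set(targets)
    disease_genes = set(disease_genes)
    if not targets or not disease_genes:
        raise ScoringError("NEAT needs nonempty sets")
    n_nodes = net.n_nodes
    if n_nodes <= max(len(targets), len(disease_genes)):
        raise ScoringError("network smaller than the gene sets")
    x = crosstalk_count(net, targets, disease_genes)
    mu, sd = neat_moments(n_nodes, len(targets), len(disease_genes))
    if sd == 0:
        raise DegenerateNullError(f"NEAT null degenerate for ({drug_id}, {disease_id})")
    z = (x - mu) / sd
    return AssociationScore(
        method="neat",
        drug_id=drug_id,
        disease_id=disease_id,
        raw=float(x),
        null_mean=mu,
        null_sd=sd,
        z=z,
        p=z_to_p(z, "higher_is_stronger"),
        direction="higher_is_stronger",
        n_targets_used=len(targets),
    )


# ---------------------------------------------------------------------------
# BinoX


def binox_score(
    net: GeneNetwork,
    targets: Iterable,
    disease_genes: Iterable,
    n_random_networks: int = 100,
    rng: np.random.Generator | None = None,
    swap_factor: float = 10.0,
    drug_id: str = "drug",
    disease_id: str = "disease",
) -> AssociationScore:
    """Crosstalk z-score under a binomial null estimated from link shuffles.

    The network is randomized ``n_random_networks`` times with
    degree-preserving double-edge swaps; p_x = mean(x_i)/n_x with n_x the
    maximum possible crosstalk, mu_b = n_x*p_x, sigma_b = sqrt(n_x*p_x*(1-p_x)).
    """
    if rng is None:
        raise ValueError("an explicit seeded numpy Generator is required")
    if n_random_networks < 1:
        raise ScoringError("n_random_networks must be >= 1")
    targets = set(targets)
    disease_genes = set(disease_genes)
    if not targets or not disease_genes:
        raise ScoringError("BinoX needs nonempty sets")
    x = crosstalk_count(net, targets, disease_genes)
    n_x = max_crosstalk(targets, disease_genes)
    xs = np.empty(n_random_networks)
    for i in range(n_random_networks):
        shuffled = shuffle_preserving_degree(net, swap_factor=swap_factor, rng=rng)
        xs[i] = crosstalk_count(shuffled, targets, disease_genes)
    return _binox_from_samples(x, n_x, xs, drug_id, disease_id, len(targets))


def _binox_from_samples(x, n_x, xs, drug_id, disease_id, n_targets) -> AssociationScore:
    p_x = float(xs.mean() / n_x) if n_x > 0 else 0.0
    if p_x <= 0.0 or p_x >= 1.0:
        raise DegenerateNullError(
            f"BinoX p_x={p_x:.3g} degenerate for ({drug_id}, {disease_id}); "
            f"raise the number of random networks"
        )
    mu = n_x * p_x
    sd = math.sqrt(n_x * p_x * (1 - p_x))
    z = (x - mu) / sd
    return AssociationScore(
        method="binox",
        drug_id=drug_id,
        disease_id=disease_id,
        raw=float(x),
        null_mean=mu,
        null_sd=sd,
        z=z,
        p=z_to_p(z, "higher_is_stronger"),
        direction="higher_is_stronger",
        n_targets_used=n_targets,
    )


# ---------------------------------------------------------------------------
# beta-binomial fitting (ANUBIX null)


@dataclass(frozen=True)
class BetaBinomialFit:
    """Maximum-likelihood beta-binomial fit BetaBin(n_trials, alpha, beta)."""

    alpha: float
    beta: float
    n_trials: int
    log_likelihood: float

    @property
    def mean(self) -> float:
        return self.n_trials * self.alpha / (self.alpha + self.beta)

    @property
    def sd(self) -> float:
        a, b, n = self.alpha, self.beta, self.n_trials
        s = a + b
        var = n * a * b * (s + n) / (s * s * (s + 1))
        return math.sqrt(var)


_FALLBACK_CONCENTRATION = 1e6  # alpha+beta when the data show no over-dispersion


def fit_betabinomial(samples: Sequence[int], n_trials: int) -> BetaBinomialFit:
    """Fit BetaBin(n_trials, alpha, beta) to counts by maximum likelihood.

    Initialized by method of moments and refined in log-parameter space.
    When the samples are under-dispersed relative to a binomial (or all
    identical) the MLE diverges toward alpha+beta = infinity; the fit then
    falls back to a near-binomial with alpha+beta = 1e6 at the sample-mean
    proportion (logged).
    """
    xs = np.asarray(samples, dtype=float)
    if xs.size == 0:
        raise ScoringError("no samples to fit")
    if n_trials < 1:
        raise ScoringError("n_trials must be positive")
    if (xs < 0).any() or (xs > n_trials).any():
        raise ScoringError("samples must lie in [0, n_trials]")

    mean = xs.mean()
    # pseudo-count keeps the proportion off the boundary for all-0/all-n data
    pi = float(np.clip((xs.sum() + 0.5) / (xs.size * n_trials + 1.0), 1e-12, 1 - 1e-12))

    def fallback(reason: str) -> BetaBinomialFit:
        logger.warning("fit_betabinomial: %s; near-binomial fallback at p=%.4g", reason, pi)
        a = pi * _FALLBACK_CONCENTRATION
        b = (1 - pi) * _FALLBACK_CONCENTRATION
        ll = float(stats.betabinom.logpmf(xs, n_trials, a, b).sum())
        return BetaBinomialFit(a, b, n_trials, ll)

    if np.all(xs == xs[0]):
        return fallback("all samples identical")
    var = xs.var(ddof=1)
    binom_var = n_trials * pi * (1 - pi)
    if var <= binom_var or n_trials < 2:
        return fallback("samples under-dispersed relative to binomial")

    # method-of-moments start: var = n*pi*(1-pi)*(1+(n-1)*rho), rho = 1/(a+b+1)
    rho = (var / binom_var - 1.0) / (n_trials - 1)
    conc = max(1.0 / min(rho, 1 - 1e-9) - 1.0, 1e-3)
    a0, b0 = pi * conc, (1 - pi) * conc

    values, counts = np.unique(xs, return_counts=True)

    def nll(theta):
        a, b = np.exp(theta)
        if not np.isfinite(a) or not np.isfinite(b):
            return np.inf
        return -float(np.dot(counts, stats.betabinom.logpmf(values, n_trials, a, b)))

    x0 = np.log([a0, b0])
    res = optimize.minimize(nll, x0, method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    best = res.x if res.fun <= nll(x0) else x0  # optimizer contract: never worse than the start
    a, b = np.exp(best)
    ll = -nll(best)
    return BetaBinomialFit(float(a), float(b), n_trials, float(ll))


def anubix_score(
    net: GeneNetwork,
    targets: Iterable,
    disease_genes: Iterable,
    bins: DegreeBins,
    n_samples: int = 100,
    rng: np.random.Generator | None = None,
    drug_id: str = "drug",
    disease_id: str = "disease",
) -> AssociationScore:
    """Crosstalk z-score under a beta-binomial null from degree-matched sampling.

    ``n_samples`` target-like sets (disease set fixed) give a crosstalk
    sample; a beta-binomial with n_trials = max_crosstalk(T, S) is fitted
    by ML and its mean/sd normalize the observed crosstalk.
    """
    if rng is None:
        raise ValueError("an explicit seeded numpy Generator is required")
    targets = set(targets)
    disease_genes = set(disease_genes)
    if not targets or not disease_genes:
        raise ScoringError("ANUBIX needs nonempty sets")
    x = crosstalk_count(net, targets, disease_genes)
    n_x = max_crosstalk(targets, disease_genes)
    if n_x < 1:
        raise DegenerateNullError(f"no possible crosstalk for ({drug_id}, {disease_id})")
    xs = np.empty(n_samples)
    for i in range(n_samples):
        t_like = sample_degree_matched(net, bins, targets, rng)
        xs[i] = min(crosstalk_count(net, t_like, disease_genes), n_x)
    fit = fit_betabinomial(xs.astype(int), n_x)
    mu, sd = fit.mean, fit.sd
    if sd == 0:
        raise DegenerateNullError(f"ANUBIX null degenerate for ({drug_id}, {disease_id})")
    z = (x - mu) / sd
    return AssociationScore(
        method="anubix",
        drug_id=drug_id,
        disease_id=disease_id,
        raw=float(x),
        null_mean=mu,
        null_sd=sd,
        z=z,
        p=z_to_p(z, "higher_is_stronger"),
        direction="higher_is_stronger",
        n_targets_used=len(targets),
    )


# ---------------------------------------------------------------------------
# all-pairs scoring (batched nulls)


def _score_row(s: AssociationScore) -> dict:
    return {
        "method": s.method,
        "drug_id": s.drug_id,
        "disease_id": s.disease_id,
        "raw": s.raw,
        "null_mean": s.null_mean,
        "null_sd": s.null_sd,
        "z": s.z,
        "p": s.p,
        "q": s.q,
        "direction": s.direction,
        "n_targets_used": s.n_targets_used,
        "status": s.status,
    }


def _na_row(method, drug_id, disease_id, direction, status) -> dict:
    return {
        "method": method,
        "drug_id": drug_id,
        "disease_id": disease_id,
        "raw": math.nan,
        "null_mean": math.nan,
        "null_sd": math.nan,
        "z": math.nan,
        "p": math.nan,
        "q": math.nan,
        "direction": direction,
        "n_targets_used": 0,
        "status": status,
    }


def _restrict_sets(net: GeneNetwork, sets: Mapping[str, set], kind: str) -> dict[str, set]:
    """Drop out-of-network members and empty sets, with logged counts."""
    out = {}
    n_dropped_members = 0
    dropped_sets = []
    for sid, members in sets.items():
        kept = set(members) & net.node_set
        n_dropped_members += len(members) - len(kept)
        if kept:
            out[sid] = kept
        else:
            dropped_sets.append(sid)
    if n_dropped_members:
        logger.info("%s: dropped %d out-of-network member(s)", kind, n_dropped_members)
    for sid in dropped_sets:
        logger.info("%s: excluded %r (no members in network)", kind, sid)
    return out


def _sample_index_matrix(
    net: GeneNetwork,
    bins: DegreeBins,
    reference_set: set,
    n_draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_draws, |reference|) node-index matrix of degree-matched samples.

    Row i is a without-replacement degree-matched sample (per-bin Gumbel
    top-k trick: take the c smallest of uniform draws over the bin).
    """
    node_index = net.node_index
    cols = []
    for b, count in sorted(bins.counts_for(reference_set).items()):
        pool = np.array([node_index[n] for n in bins.bins[b]])
        r = rng.random((n_draws, pool.size))
        sel = np.argpartition(r, count - 1, axis=1)[:, :count]
        cols.append(pool[sel])
    return np.concatenate(cols, axis=1)


def _neighbors_in_set_counts(net: GeneNetwork, node_set: set) -> np.ndarray:
    """c[i] = |N(node_i) ∩ node_set| for every node index i."""
    mask = np.zeros(net.n_nodes, dtype=np.float64)
    for n in node_set:
        mask[net.node_index[n]] = 1.0
    return net._adjacency_csr().dot(mask)


def score_all_pairs(
    net: GeneNetwork,
    drugs: Mapping[str, set],
    diseases: Mapping[str, set],
    method: str,
    rng: np.random.Generator | None = None,
    n_perm: int = 1000,
    n_samples: int = 100,
    n_random_networks: int = 100,
    swap_factor: float = 10.0,
    bin_size: int = 100,
    bins: DegreeBins | None = None,
    pairs: set | None = None,
) -> pd.DataFrame:
    """Score every (drug, disease) combination with one method.

    ``pairs`` optionally restricts scoring to a subset of (drug_id,
    disease_id) tuples while still sharing the batched nulls.

    Returns one row per pair in the standard score-table schema. Members
    absent from the network are dropped with logged counts; drugs with no
    in-network target are excluded (logged). Degenerate pairs are emitted
    with z = NaN and a status code instead of aborting the run.

    Null computation is batched for throughput: BinoX randomizes the
    network once and reuses the shuffles for all pairs (as the original
    tool does); proximity reuses each permutation's sampled disease-like
    set across drugs of the same disease (marginally identical null).
    Deterministic given ``rng``.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if method != "neat" and rng is None:
        raise ValueError(f"{method} is stochastic: an explicit seeded Generator is required")
    drugs = _restrict_sets(net, drugs, "drugs")
    diseases = _restrict_sets(net, diseases, "diseases")
    if bins is None and method in ("proximity", "anubix"):
        bins = build_degree_bins(net, bin_size=bin_size)

    def _drug_items(did):
        return [
            (d, t) for d, t in drugs.items() if pairs is None or (d, did) in pairs
        ]

    rows: list[dict] = []
    if method == "neat":
        for did, genes in diseases.items():
            for drug, targets in _drug_items(did):
                try:
                    rows.append(_score_row(neat_score(net, targets, genes, drug, did)))
                except DegenerateNullError:
                    rows.append(_na_row(method, drug, did, "higher_is_stronger", "degenerate_null"))

    elif method == "binox":
        shuffles = []
        for _ in range(n_random_networks):
            shuffles.append(shuffle_preserving_degree(net, swap_factor=swap_factor, rng=rng))
        for did, genes in diseases.items():
            for drug, targets in _drug_items(did):
                x = crosstalk_count(net, targets, genes)
                n_x = max_crosstalk(targets, genes)
                xs = np.array(
                    [crosstalk_count(sh, targets, genes) for sh in shuffles], dtype=float
                )
                try:
                    rows.append(
                        _score_row(
                            _binox_from_samples(x, n_x, xs, drug, did, len(targets))
                        )
                    )
                except DegenerateNullError:
                    rows.append(_na_row(method, drug, did, "higher_is_stronger", "degenerate_null"))

    elif method == "anubix":
        for did, genes in diseases.items():
            items = _drug_items(did)
            if not items:
                continue
            nbr = _neighbors_in_set_counts(net, genes)
            genes_idx = {net.node_index[g] for g in genes}
            for drug, targets in items:
                x = crosstalk_count(net, targets, genes)
                n_x = max_crosstalk(targets, genes)
                if n_x < 1:
                    rows.append(_na_row(method, drug, did, "higher_is_stronger", "degenerate_null"))
                    continue
                tmat = _sample_index_matrix(net, bins, targets, n_samples, rng)
                xs = nbr[tmat].sum(axis=1)
                # correct rows whose sample overlaps the disease set
                # (edges inside the overlap were counted twice)
                nodelist = net.nodelist
                for i in range(n_samples):
                    row_idx = tmat[i]
                    inter = [j for j in row_idx if j in genes_idx]
                    if len(inter) >= 2:
                        sampled = {nodelist[j] for j in row_idx}
                        xs[i] = crosstalk_count(net, sampled, genes)
                xs = np.minimum(xs, n_x)
                try:
                    fit = fit_betabinomial(xs.astype(int), n_x)
                    if fit.sd == 0:
                        raise DegenerateNullError("zero-sd fit")
                    z = (x - fit.mean) / fit.sd
                    rows.append(
                        _score_row(
                            AssociationScore(
                                method="anubix",
                                drug_id=drug,
                                disease_id=did,
                                raw=float(x),
                                null_mean=fit.mean,
                                null_sd=fit.sd,
                                z=z,
                                p=z_to_p(z, "higher_is_stronger"),
                                direction="higher_is_stronger",
                                n_targets_used=len(targets),
                            )
                        )
                    )
                except DegenerateNullError:
                    rows.append(_na_row(method, drug, did, "higher_is_stronger", "degenerate_null"))

    else:  # proximity
        idx = net.node_index
        for did, genes in diseases.items():
            items = _drug_items(did)
            if not items:
                continue
            # one distance array per permutation's disease-like sample,
            # shared across all drugs for this disease
            dist_null = np.empty((n_perm, net.n_nodes), dtype=np.float32)
            for i in range(n_perm):
                s_like = sample_degree_matched(net, bins, genes, rng)
                dist_null[i] = net.hop_distance_array(s_like)
            dist_obs = net.hop_distance_array(genes)
            for drug, targets in items:
                t_idx = np.array([idx[t] for t in targets])
                obs_vals = dist_obs[t_idx]
                obs_finite = obs_vals[np.isfinite(obs_vals)]
                if obs_finite.size == 0:
                    rows.append(_na_row(method, drug, did, "lower_is_stronger", "unreachable"))
                    continue
                if obs_finite.size < obs_vals.size:
                    logger.warning(
                        "proximity: %d/%d target(s) of %r unreachable from %r",
                        obs_vals.size - obs_finite.size, obs_vals.size, drug, did,
                    )
                d_obs = float(obs_finite.mean())
                tmat = _sample_index_matrix(net, bins, targets, n_perm, rng)
                vals = np.take_along_axis(dist_null, tmat, axis=1)
                with np.errstate(invalid="ignore"):
                    masked = np.ma.masked_invalid(vals)
                    d_null = masked.mean(axis=1).filled(np.nan)
                d_null = d_null[np.isfinite(d_null)]
                if d_null.size == 0 or d_null.std() == 0:
                    rows.append(_na_row(method, drug, did, "lower_is_stronger", "degenerate_null"))
                    continue
                mu, sd = float(d_null.mean()), float(d_null.std())
                z = (d_obs - mu) / sd
                rows.append(
                    _score_row(
                        AssociationScore(
                            method="proximity",
                            drug_id=drug,
                            disease_id=did,
                            raw=d_obs,
                            null_mean=mu,
                            null_sd=sd,
                            z=z,
                            p=z_to_p(z, "lower_is_stronger"),
                            direction="lower_is_stronger",
                            n_targets_used=len(targets),
                            p_empirical=float((1 + (d_null <= d_obs).sum()) / (d_null.size + 1)),
                        )
                    )
                )

    n_excluded = sum(1 for r in rows if r["status"] != "ok")
    if n_excluded:
        logger.info("score_all_pairs(%s): %d pair(s) not scored", method, n_excluded)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# drug–drug similarity


def _combine_similarity(zs: Sequence[float], method: str) -> float:
    zs = [z for z in zs if np.isfinite(z)]
    if not zs:
        raise ScoringError("no usable reference z-scores for similarity")
    if method == "proximity":
        return float(math.exp(-min(zs)))
    return float(max(zs))


def drug_drug_similarity(
    method: str,
    net: GeneNetwork,
    candidate_targets: Iterable,
    approved_target_sets: Sequence[Iterable],
    bins: DegreeBins | None = None,
    rng: np.random.Generator | None = None,
    leave_one_out: bool = True,
    n_perm: int = 1000,
    n_samples: int = 100,
    n_random_networks: int = 100,
) -> float:
    """Similarity of a candidate drug to the drugs approved for a disease.

    The method's z is computed between the candidate's target set and each
    approved drug's target set (target sets play both roles); the combined
    similarity is e^(−min z) for proximity and max z for the crosstalk
    methods. With ``leave_one_out`` (default), approved sets identical to
    the candidate's are excluded.
    """
    candidate = set(candidate_targets)
    refs = [set(s) for s in approved_target_sets]
    if leave_one_out:
        refs = [s for s in refs if s != candidate]
    if not refs:
        raise ScoringError("no approved reference drugs left after self-exclusion")
    if bins is None and method in ("proximity", "anubix"):
        bins = build_degree_bins(net)
    zs = []
    for ref in refs:
        if method == "proximity":
            s = proximity_score(net, candidate, ref, bins, n_perm=n_perm, rng=rng)
        elif method == "neat":
            s = neat_score(net, candidate, ref)
        elif method == "binox":
            s = binox_score(net, candidate, ref, n_random_networks=n_random_networks, rng=rng)
        elif method == "anubix":
            s = anubix_score(net, candidate, ref, bins, n_samples=n_samples, rng=rng)
        else:
            raise ValueError(f"unknown method {method!r}")
        zs.append(s.z)
    return _combine_similarity(zs, method)


def similarity_table(
    net: GeneNetwork,
    drugs: Mapping[str, set],
    diseases_to_approved: Mapping[str, Sequence[str]],
    method: str,
    rng: np.random.Generator | None = None,
    leave_one_out: bool = True,
    **score_kwargs,
) -> pd.DataFrame:
    """Drug–disease similarity scores for every (candidate, disease) pair.

    ``diseases_to_approved`` maps each disease to the ids of drugs approved
    for it; those drugs' target sets are the references. The candidate ×
    reference z-matrix is computed once with :func:`score_all_pairs`
    (references acting as the "disease" sets) and reused across diseases.
    Pairs whose reference list is empty after self-exclusion get NaN.
    """
    ref_ids = sorted({d for refs in diseases_to_approved.values() for d in refs})
    missing = [d for d in ref_ids if d not in drugs]
    if missing:
        raise ScoringError(f"approved drug(s) without target sets: {missing[:5]}")
    ztab = score_all_pairs(
        net,
        drugs=drugs,
        diseases={rid: drugs[rid] for rid in ref_ids},
        method=method,
        rng=rng,
        **score_kwargs,
    )
    zmat = ztab.pivot(index="drug_id", columns="disease_id", values="z")
    rows = []
    for did, refs in diseases_to_approved.items():
        for cand in drugs:
            usable = [
                r
                for r in refs
                if r in zmat.columns
                and not (leave_one_out and (r == cand or drugs[r] == drugs[cand]))
            ]
            zs = [zmat.loc[cand, r] for r in usable if cand in zmat.index]
            try:
                sim = _combine_similarity(zs, method)
                status = "ok"
            except ScoringError:
                sim = math.nan
                status = "no_reference"
            rows.append(
                {
                    "method": method,
                    "drug_id": cand,
                    "disease_id": did,
                    "similarity": sim,
                    "n_references": len(usable),
                    "status": status,
                }
            )
    return pd.DataFrame(rows)
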