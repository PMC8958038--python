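"""Unit tests for the four scorers, the beta-binomial fit and similarity."""

import logging
import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from netrepurpose.network import GeneNetwork, build_degree_bins
from netrepurpose.scoring import (
    AssociationScore,
    DegenerateNullError,
    ScoringError,
    _combine_similarity,
    anubix_score,
    binox_score,
    drug_drug_similarity,
    fit_betabinomial,
    neat_score,
    oriented_score,
    proximity_distance,
    proximity_score,
    score_all_pairs,
    z_to_p,
)

from conftest import brute_hypergeom_moments


# ---------------------------------------------------------------------------
# proximity


class TestProximityDistance:
    def test_targets_inside_disease_set_give_zero(self, path5):
        assert proximity_distance(path5, {"2", "3"}, {"1", "2", "3"}) == 0.0

    def test_mean_over_targets(self, path5):
        assert proximity_distance(path5, {"1", "5"}, {"3"}) == 2.0

    def test_min_over_disease_genes(self):
        net = GeneNetwork.from_edges([("1", "2"), ("2", "3")])
        assert proximity_distance(net, {"1"}, {"2", "3"}) == 1.0

    def test_unreachable_target_excluded(self):
        net = GeneNetwork.from_edges([("a", "b"), ("x", "y")])
        assert proximity_distance(net, {"a", "x"}, {"b"}) == 1.0

    def test_fully_unreachable_raises(self):
        net = GeneNetwork.from_edges([("a", "b"), ("x", "y")])
        with pytest.raises(ScoringError):
            proximity_distance(net, {"x"}, {"b"})

    def test_empty_sets_raise(self, path5):
        with pytest.raises(ScoringError):
            proximity_distance(path5, set(), {"1"})


class TestProximityScore:
    def test_deterministic_given_seed(self, ba300):
        bins = build_degree_bins(ba300, 50)
        kw = dict(n_perm=100)
        s1 = proximity_score(ba300, {"g000", "g010"}, {"g001", "g002", "g020"}, bins,
                             rng=np.random.default_rng(4), **kw)
        s2 = proximity_score(ba300, {"g000", "g010"}, {"g001", "g002", "g020"}, bins,
                             rng=np.random.default_rng(4), **kw)
        assert s1.z == s2.z and s1.p_empirical == s2.p_empirical

    def test_neighbors_of_disease_genes_score_negative(self, ba300):
        # targets adjacent to the disease genes: shorter-than-null distance
        bins = build_degree_bins(ba300, 50)
        rng = np.random.default_rng(0)
        genes = set(sorted(ba300.node_set, key=lambda n: (ba300.degree(n), n))[-20:])
        adj = ba300.adjacency()
        targets = set()
        for g in sorted(genes):
            targets |= set(sorted(adj[g]))
            if len(targets) >= 4:
                break
        targets = set(sorted(targets)[:4]) - genes
        s = proximity_score(ba300, targets, genes, bins, n_perm=300, rng=rng)
        assert s.direction == "lower_is_stronger"
        assert s.z < 0
        assert oriented_score(s) > 0


# ---------------------------------------------------------------------------
# NEAT


class TestNeat:
    def test_printed_formula_moments(self, path5):
        s = neat_score(path5, {"1"}, {"2", "3"})
        assert s.null_mean == pytest.approx(0.4)
        assert s.null_sd == pytest.approx(math.sqrt(0.24))

    def test_zero_crosstalk_at_mean_gives_zero_z(self):
        # build a case where x equals mu_H: N=4, K=1, n=2, x = 0.5 unreachable;
        # instead check z sign around the mean analytically
        net = GeneNetwork.from_edges([("1", "2"), ("3", "4")])
        s = neat_score(net, {"1"}, {"3", "4"})  # x=0, mu=0.5
        assert s.raw == 0.0
        assert s.z == pytest.approx((0 - 0.5) / s.null_sd)

    @pytest.mark.parametrize("n_nodes,k,n", [(50, 5, 10), (200, 3, 40), (1000, 7, 100)])
    def test_moments_match_scipy_hypergeom(self, n_nodes, k, n):
        g = nx.gnp_random_graph(n_nodes, 0.05, seed=1)
        net = GeneNetwork(nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes}))
        nodes = sorted(net.node_set)
        s = neat_score(net, set(nodes[:k]), set(nodes[k : k + n]))
        mu, sd = brute_hypergeom_moments(n_nodes, k, n)
        assert s.null_mean == pytest.approx(mu, abs=1e-12)
        assert s.null_sd == pytest.approx(sd, abs=1e-12)

    def test_direction_and_p(self, path5):
        s = neat_score(path5, {"1"}, {"2"})
        assert s.direction == "higher_is_stronger"
        assert s.p == pytest.approx(stats.norm.sf(s.z))


# ---------------------------------------------------------------------------
# BinoX


class TestBinox:
    def test_deterministic_given_seed(self, ba300):
        kw = dict(n_random_networks=20)
        a = binox_score(ba300, {"g000"}, {"g001", "g002"}, rng=np.random.default_rng(8), **kw)
        b = binox_score(ba300, {"g000"}, {"g001", "g002"}, rng=np.random.default_rng(8), **kw)
        assert a.z == b.z

    def test_p_x_within_sample_bounds(self, ba300):
        s = binox_score(ba300, {"g000", "g005"}, {"g001", "g002", "g003"},
                        n_random_networks=30, rng=np.random.default_rng(8))
        n_x = 6
        assert 0 < s.null_mean < n_x

    def test_degenerate_p_x_raises_with_guidance(self):
        # two far-apart dumbbells: shuffles of a 2-edge graph cannot connect the sets
        net = GeneNetwork.from_edges([("a", "b"), ("x", "y")])
        with pytest.raises(DegenerateNullError, match="random networks"):
            binox_score(net, {"a"}, {"x"}, n_random_networks=5,
                        rng=np.random.default_rng(0))


# ---------------------------------------------------------------------------
# beta-binomial


class TestFitBetaBinomial:
    def test_recovers_generating_parameters(self):
        rng = np.random.default_rng(12)
        xs = stats.betabinom.rvs(100, 2.0, 5.0, size=1000, random_state=rng)
        fit = fit_betabinomial(xs, 100)
        assert 1.6 <= fit.alpha <= 2.4
        assert 4.0 <= fit.beta <= 6.0

    def test_symmetric_parameters_give_central_mean(self):
        rng = np.random.default_rng(5)
        xs = stats.betabinom.rvs(60, 3.0, 3.0, size=800, random_state=rng)
        fit = fit_betabinomial(xs, 60)
        assert fit.mean == pytest.approx(30, rel=0.05)

    def test_likelihood_not_worse_than_moment_start(self):
        rng = np.random.default_rng(7)
        xs = stats.betabinom.rvs(50, 1.5, 8.0, size=500, random_state=rng)
        fit = fit_betabinomial(xs, 50)
        ll_true = stats.betabinom.logpmf(xs, 50, 1.5, 8.0).sum()
        assert fit.log_likelihood >= ll_true - 1e-6

    def test_underdispersed_falls_back_to_near_binomial(self, caplog):
        rng = np.random.default_rng(3)
        xs = rng.binomial(40, 0.2, size=500)
        with caplog.at_level(logging.WARNING):
            fit = fit_betabinomial(xs, 40)
        assert fit.alpha + fit.beta >= 1e5
        assert fit.mean == pytest.approx(xs.mean(), rel=0.05)

    def test_constant_samples_fall_back(self):
        fit = fit_betabinomial([3] * 20, 10)
        assert fit.alpha + fit.beta >= 1e5

    def test_out_of_range_samples_rejected(self):
        with pytest.raises(ScoringError):
            fit_betabinomial([11], 10)

    def test_fit_moments_match_closed_form(self):
        fit = fit_betabinomial([0, 1, 2, 5, 9, 3, 2, 1], 10)
        a, b, n = fit.alpha, fit.beta, fit.n_trials
        assert fit.mean == pytest.approx(n * a / (a + b))
        var = n * a * b * (a + b + n) / ((a + b) ** 2 * (a + b + 1))
        assert fit.sd == pytest.approx(math.sqrt(var))


# ---------------------------------------------------------------------------
# ANUBIX


class TestAnubix:
    def test_deterministic_given_seed(self, ba300):
        bins = build_degree_bins(ba300, 50)
        a = anubix_score(ba300, {"g000", "g004"}, {"g001", "g002", "g010"}, bins,
                         n_samples=50, rng=np.random.default_rng(2))
        b = anubix_score(ba300, {"g000", "g004"}, {"g001", "g002", "g010"}, bins,
                         n_samples=50, rng=np.random.default_rng(2))
        assert a.z == b.z

    def test_planted_crosstalk_scores_positive(self, ba300):
        # choose targets that are neighbors of the disease genes: excess links
        bins = build_degree_bins(ba300, 50)
        genes = set(sorted(ba300.node_set, key=lambda n: (ba300.degree(n), n))[-15:])
        adj = ba300.adjacency()
        targets = set()
        for g in sorted(genes):
            for u in sorted(adj[g]):
                if u not in genes:
                    targets.add(u)
            if len(targets) >= 5:
                break
        targets = set(sorted(targets)[:5])
        s = anubix_score(ba300, targets, genes, bins, n_samples=100,
                         rng=np.random.default_rng(6))
        assert s.z > 0
        assert s.direction == "higher_is_stronger"


# ---------------------------------------------------------------------------
# plumbing


class TestOrientationAndP:
    def test_oriented_score_flips_proximity_only(self):
        prox = AssociationScore("proximity", "d", "s", 1.0, 2.0, 0.5, -2.0, 0.02,
                                "lower_is_stronger")
        anub = AssociationScore("anubix", "d", "s", 9.0, 3.0, 2.0, 3.0, 0.001,
                                "higher_is_stronger")
        assert oriented_score(prox) == 2.0
        assert oriented_score(anub) == 3.0

    def test_z_to_p_tails(self):
        assert z_to_p(0.0, "higher_is_stronger") == pytest.approx(0.5)
        assert z_to_p(1.6449, "higher_is_stronger") == pytest.approx(0.05, abs=1e-4)
        assert z_to_p(-1.6449, "lower_is_stronger") == pytest.approx(0.05, abs=1e-4)
        # p decreases as oriented evidence grows
        assert z_to_p(2.0, "higher_is_stronger") < z_to_p(1.0, "higher_is_stronger")
        assert z_to_p(-2.0, "lower_is_stronger") < z_to_p(-1.0, "lower_is_stronger")


class TestCombineSimilarity:
    def test_proximity_uses_exp_neg_min(self):
        assert _combine_similarity([2.0, -1.0], "proximity") == pytest.approx(math.e)
        assert _combine_similarity([0.0], "proximity") == pytest.approx(1.0)

    def test_crosstalk_uses_max(self):
        assert _combine_similarity([2.0, -1.0], "anubix") == 2.0


class TestDrugDrugSimilarity:
    def test_leave_one_out_excludes_identical_set(self, ba300):
        cand = {"g000", "g001"}
        with pytest.raises(ScoringError):
            drug_drug_similarity("neat", ba300, cand, [cand])

    def test_self_similarity_maximal_without_loo(self, ba300):
        # with leave-one-out off, a candidate identical to an approved drug
        # has maximal crosstalk-based similarity among candidates
        hub = max(ba300.node_set, key=ba300.degree)
        cand = set(sorted(ba300.adjacency()[hub])[:3]) | {hub}
        others = [{n} for n in sorted(ba300.node_set)[:3]]
        sim_self = drug_drug_similarity("neat", ba300, cand, [cand] + others,
                                        leave_one_out=False)
        sims = [
            drug_drug_similarity("neat", ba300, o, [cand] + others, leave_one_out=False)
            for o in others
        ]
        assert sim_self >= max(sims)


class TestScoreAllPairs:
    def test_row_per_combination(self, ba300):
        drugs = {"d1": {"g000"}, "d2": {"g001", "g002"}}
        dis = {"s1": {"g003"}, "s2": {"g004"}, "s3": {"g005", "g006"}}
        tab = score_all_pairs(ba300, drugs, dis, "neat")
        assert len(tab) == 6
        assert set(tab["method"]) == {"neat"}

    def test_out_of_network_drug_excluded_and_logged(self, ba300, caplog):
        drugs = {"d1": {"g000"}, "ghost": {"zz"}}
        dis = {"s1": {"g003"}}
        with caplog.at_level(logging.INFO):
            tab = score_all_pairs(ba300, drugs, dis, "neat")
        assert len(tab) == 1
        assert "ghost" in caplog.text

    @pytest.mark.parametrize("method", ["proximity", "anubix", "binox"])
    def test_rerun_identical_with_same_seed(self, ba300, method):
        drugs = {"d1": {"g000"}, "d2": {"g001", "g010"}}
        dis = {"s1": {"g003", "g004", "g005"}}
        kw = dict(n_perm=50, n_samples=30, n_random_networks=10)
        t1 = score_all_pairs(ba300, drugs, dis, method, rng=np.random.default_rng(9), **kw)
        t2 = score_all_pairs(ba300, drugs, dis, method, rng=np.random.default_rng(9), **kw)
        assert t1.equals(t2)

    def test_stochastic_method_requires_rng(self, ba300):
        with pytest.raises(ValueError, match="seeded"):
            score_all_pairs(ba300, {"d": {"g000"}}, {"s": {"g001"}}, "proximity")
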