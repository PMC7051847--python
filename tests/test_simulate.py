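"""Synthetic Ising data: exact enumeration, Gibbs sampling, NPI-like networks."""

import numpy as np
import pytest

from isingnet.data import npi_metadata, summarize_total_scores
from isingnet.model import fit_ising
from isingnet.network import IsingNetwork
from isingnet.simulate import (
    GeneratorSpec,
    compare_networks,
    exact_distribution,
    gibbs_sample,
    npi_like_network,
    sample_npi_like,
)


def empirical_state_freqs(data, p):
    codes = data.values @ (2 ** np.arange(p - 1, -1, -1))
    return np.bincount(codes, minlength=2**p) / data.n


def exact_state_probs(net):
    ex = exact_distribution(net)
    codes = ex.states @ (2 ** np.arange(net.p - 1, -1, -1))
    out = np.zeros(2**net.p)
    out[codes] = ex.probabilities
    return out


class TestExactDistribution:
    def test_single_free_node_is_fair_coin(self):
        net = IsingNetwork(np.zeros(1), np.zeros((1, 1)))
        ex = exact_distribution(net)
        assert ex.probabilities == pytest.approx([0.5, 0.5])

    def test_two_independent_nodes_are_uniform(self):
        net = IsingNetwork(np.zeros(2), np.zeros((2, 2)))
        np.testing.assert_allclose(exact_distribution(net).probabilities, 0.25)

    def test_two_coupled_nodes_match_enumeration_by_hand(self):
        # tau = 0, omega12 = 1: weights {1, 1, 1, e}, so P(1,1) = e / (3 + e)
        net = IsingNetwork(np.zeros(2), np.array([[0.0, 1.0], [1.0, 0.0]]))
        ex = exact_distribution(net)
        both = np.all(ex.states == 1, axis=1)
        assert ex.probabilities[both][0] == pytest.approx(np.e / (3 + np.e))

    def test_two_node_marginal_closed_form(self):
        tau = np.array([0.4, -0.7])
        omega = np.array([[0.0, 0.9], [0.9, 0.0]])
        net = IsingNetwork(tau, omega)
        z = (
            1.0
            + np.exp(tau[0])
            + np.exp(tau[1])
            + np.exp(tau[0] + tau[1] + omega[0, 1])
        )
        expected = (np.exp(tau[0]) + np.exp(tau[0] + tau[1] + omega[0, 1])) / z
        assert exact_distribution(net).marginal(0) == pytest.approx(expected)

    def test_probabilities_sum_to_one(self, net4):
        assert exact_distribution(net4).probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_large_p_refused_with_pointer_to_gibbs(self):
        net = IsingNetwork(np.zeros(16), np.zeros((16, 16)))
        with pytest.raises(ValueError, match="gibbs"):
            exact_distribution(net)


class TestGibbsSampler:
    def test_same_seed_reproduces_dataset(self, net4):
        a = gibbs_sample(net4, 50, seed=5)
        b = gibbs_sample(net4, 50, seed=5)
        assert np.array_equal(a.values, b.values)
        c = gibbs_sample(net4, 50, seed=6)
        assert not np.array_equal(a.values, c.values)

    def test_independent_fair_coins_have_half_means(self):
        net = IsingNetwork(np.zeros(5), np.zeros((5, 5)))
        data = gibbs_sample(net, 4000, seed=8)
        tol = 3 * np.sqrt(0.25 / data.n)
        assert np.all(np.abs(data.values.mean(axis=0) - 0.5) < tol)

    def test_chain_approaches_exact_distribution(self, net4):
        exact = exact_state_probs(net4)
        data = gibbs_sample(net4, 50_000, seed=17)
        tv = 0.5 * np.abs(empirical_state_freqs(data, 4) - exact).sum()
        assert tv < 0.02

    def test_rejects_bad_chain_settings(self, net4):
        with pytest.raises(ValueError):
            gibbs_sample(net4, 0, seed=1)
        with pytest.raises(ValueError):
            gibbs_sample(net4, 5, thin=0, seed=1)


class TestNpiLikeNetwork:
    def test_default_spec_reproduces_domain_structure(self):
        net = npi_like_network(GeneratorSpec())
        assert net.p == 40
        assert net.labels == tuple(item.label for item in npi_metadata())
        from isingnet.data import npi_domain_blocks

        by_domain = npi_domain_blocks()
        assert [len(v) for v in by_domain.values()] == [8, 7, 5, 6, 5, 6, 3]
        for members in by_domain.values():
            for a_pos, i in enumerate(members):
                for j in members[a_pos + 1:]:
                    assert net.omega[i, j] > 0  # within-domain couplings positive
        assert np.all(net.tau < 0)

    def test_no_negative_edges_when_count_zero(self):
        net = npi_like_network(GeneratorSpec(negative_edge_count=0, seed=4))
        assert np.all(net.omega >= 0)

    def test_default_spec_has_requested_negative_edges(self):
        net = npi_like_network(GeneratorSpec(seed=0))
        iu = np.triu_indices(40, k=1)
        assert (net.omega[iu] < 0).sum() == GeneratorSpec().negative_edge_count

    def test_infeasible_negative_count_raises(self):
        with pytest.raises(ValueError, match="negative_edge_count"):
            npi_like_network(GeneratorSpec(cross_block_density=0.0, negative_edge_count=2))

    def test_block_sizes_must_partition_p(self):
        with pytest.raises(ValueError, match="sum"):
            GeneratorSpec(p=10, block_sizes=(5, 4))

    def test_network_depends_on_seed_but_not_sample_size(self):
        a = npi_like_network(GeneratorSpec(seed=1, n=100))
        b = npi_like_network(GeneratorSpec(seed=1, n=9999))
        c = npi_like_network(GeneratorSpec(seed=2, n=100))
        np.testing.assert_array_equal(a.omega, b.omega)
        assert not np.array_equal(a.omega, c.omega)

    def test_calibrated_mean_total_score(self):
        """Default thresholds put the mean score near 13 of 40."""
        data, _ = sample_npi_like(GeneratorSpec(seed=0, n=2000))
        mean, _ = summarize_total_scores(data)
        assert 11.0 <= mean <= 15.0


class TestRecovery:
    def test_metrics_invariant_under_relabeling(self):
        rng = np.random.default_rng(2)
        p = 6
        omega = np.zeros((p, p))
        omega[0, 1] = omega[1, 0] = 1.0
        omega[2, 3] = omega[3, 2] = -0.8
        truth = IsingNetwork(np.zeros(p), omega)
        est_omega = omega * rng.uniform(0.5, 1.0)
        est = IsingNetwork(np.zeros(p), est_omega)
        base = compare_networks(truth, est)
        perm = rng.permutation(p)
        permute = lambda net: IsingNetwork(
            net.tau[perm], net.omega[np.ix_(perm, perm)],
            tuple(net.labels[i] for i in perm),
        )
        permuted = compare_networks(permute(truth), permute(est))
        assert base.sensitivity == permuted.sensitivity
        assert base.specificity == permuted.specificity
        assert base.weight_correlation == pytest.approx(permuted.weight_correlation)

    def test_single_strong_edge_always_detected(self):
        """One omega=2 edge among 5 nodes is found in >= 18 of 20 replications."""
        omega = np.zeros((5, 5))
        omega[0, 1] = omega[1, 0] = 2.0
        net = IsingNetwork(np.full(5, -0.5), omega)
        hits = 0
        for seed in range(20):
            data = gibbs_sample(net, 2000, seed=seed)
            hits += compare_networks(net, fit_ising(data)).sensitivity == 1.0
        assert hits >= 18
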