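"""Bootstrap machinery: CIs, difference tests, case-dropping, CS-coefficient."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isingnet.model import EstimationConfig, fit_ising
from isingnet.stability import (
    CaseDropResult,
    EdgeBootstrap,
    _one_casedrop_replicate,
    _replicate_correlation,
    bootstrap_network,
    case_dropping_bootstrap,
    centrality_difference_test,
    cs_coefficient,
    edge_ci,
    edge_difference_test,
)


def make_boot(edges: np.ndarray, strengths: np.ndarray | None = None, p: int = 3):
    """EdgeBootstrap built from explicit replicate matrices."""
    B = edges.shape[0]
    if strengths is None:
        strengths = np.zeros((B, p))
    index = tuple((i, j) for i in range(p) for j in range(i + 1, p))
    return EdgeBootstrap(
        B=B,
        edge_index=index,
        replicate_edges=edges,
        replicate_strength=strengths,
        labels=tuple(f"V{i+1}" for i in range(p)),
        seed=0,
        estimation_config=EstimationConfig(),
    )


class TestEdgeCI:
    def test_identical_replicates_give_zero_width(self):
        edges = np.tile([0.3, -0.1, 0.0], (25, 1))
        cis = edge_ci(make_boot(edges), 0.95)
        np.testing.assert_allclose(cis[:, 0], cis[:, 1])
        np.testing.assert_allclose(cis[:, 0], [0.3, -0.1, 0.0])

    def test_decile_replicates_match_hand_percentiles(self):
        from isingnet.stability import _percentile_ci

        reps = np.arange(0.1, 1.05, 0.1)
        # linear-interpolation quantiles of 0.1..1.0 at 10% and 90%
        lo, hi = _percentile_ci(reps, level=0.8)
        assert lo == pytest.approx(0.19)
        assert hi == pytest.approx(0.91)

    def test_wider_level_never_narrows_interval(self):
        rng = np.random.default_rng(0)
        edges = rng.normal(size=(60, 3))
        boot = make_boot(edges)
        narrow = edge_ci(boot, 0.8)
        wide = edge_ci(boot, 0.95)
        assert np.all(wide[:, 0] <= narrow[:, 0] + 1e-12)
        assert np.all(wide[:, 1] >= narrow[:, 1] - 1e-12)

    def test_endpoints_come_from_sorted_replicates(self):
        rng = np.random.default_rng(1)
        edges = rng.normal(size=(40, 3))
        boot = make_boot(edges)
        cis = edge_ci(boot, 0.9)
        for e in range(3):
            srt = np.sort(edges[:, e])
            np.testing.assert_allclose(
                cis[e], np.quantile(srt, [0.05, 0.95]), atol=1e-12
            )

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="20"):
            edge_ci(make_boot(np.zeros((5, 3))))


class TestDifferenceTests:
    def test_edge_against_itself_is_never_significant(self):
        rng = np.random.default_rng(2)
        boot = make_boot(rng.normal(size=(50, 3)))
        res = edge_difference_test(boot, (0, 1), (0, 1))
        assert not res.significant
        assert res.ci_low == res.ci_high == 0.0

    def test_separated_replicates_are_significant(self):
        rng = np.random.default_rng(3)
        edges = np.zeros((50, 3))
        edges[:, 0] = 0.4 + 0.02 * rng.random(50)  # A - B in [0.3, 0.5]
        edges[:, 1] = 0.1 - 0.02 * rng.random(50)
        res = edge_difference_test(make_boot(edges), (0, 1), (0, 2))
        assert res.significant and res.ci_low > 0.2

    def test_order_of_arguments_does_not_change_verdict(self):
        rng = np.random.default_rng(4)
        boot = make_boot(rng.normal(size=(80, 3)))
        ab = edge_difference_test(boot, (0, 1), (1, 2))
        ba = edge_difference_test(boot, (1, 2), (0, 1))
        assert ab.significant == ba.significant
        assert ab.ci_low == pytest.approx(-ba.ci_high)

    def test_centrality_test_mirrors_edge_test_semantics(self):
        strengths = np.zeros((50, 3))
        strengths[:, 0] = 1.0
        strengths[:, 1] = np.linspace(0.2, 0.4, 50)
        boot = make_boot(np.zeros((50, 3)), strengths)
        assert centrality_difference_test(boot, 0, 1).significant
        assert not centrality_difference_test(boot, "V1", "V1").significant
        by_label = centrality_difference_test(boot, "V1", "V2")
        assert by_label.significant and by_label.pair == ("V1", "V2")


class TestBootstrapNetwork:
    def test_fixed_seed_is_bit_reproducible_and_jobs_invariant(self, data10, fast_config):
        small = data10.subset(np.arange(150))
        a = bootstrap_network(small, B=3, seed=42, config=fast_config)
        b = bootstrap_network(small, B=3, seed=42, config=fast_config)
        c = bootstrap_network(small, B=3, seed=42, config=fast_config, n_jobs=2)
        np.testing.assert_array_equal(a.replicate_edges, b.replicate_edges)
        np.testing.assert_array_equal(a.replicate_edges, c.replicate_edges)
        d = bootstrap_network(small, B=3, seed=43, config=fast_config)
        assert not np.array_equal(a.replicate_edges, d.replicate_edges)

    def test_replicate_shapes_and_strength_consistency(self, data10, fast_config):
        small = data10.subset(np.arange(150))
        boot = bootstrap_network(small, B=2, seed=7, config=fast_config)
        E = 10 * 9 // 2
        assert boot.replicate_edges.shape == (2, E)
        assert boot.replicate_strength.shape == (2, 10)
        # strength of each replicate equals the absolute row sums of its edges
        for b in range(2):
            omega = np.zeros((10, 10))
            iu = np.triu_indices(10, k=1)
            omega[iu] = boot.replicate_edges[b]
            omega += omega.T
            np.testing.assert_allclose(
                boot.replicate_strength[b], np.abs(omega).sum(axis=1)
            )

    def test_true_zero_edge_interval_covers_zero(self, net4, fast_config):
        """Percentile CIs of a truly absent coupling contain 0 in >= 18/20 runs."""
        from isingnet.simulate import gibbs_sample

        covered = 0
        pos = None
        for rep in range(20):
            data = gibbs_sample(net4, 300, seed=100 + rep)
            boot = bootstrap_network(data, B=20, seed=rep, config=fast_config)
            pos = boot.edge_position((0, 3))  # omega[0, 3] = 0 in truth
            lo, hi = np.quantile(boot.replicate_edges[:, pos], [0.025, 0.975])
            covered += lo <= 0.0 <= hi
        assert covered >= 18


class TestCaseDropping:
    def test_full_size_subsample_correlates_perfectly(self, data10, fast_config):
        full = np.abs(fit_ising(data10, fast_config).omega).sum(axis=1)
        corr = _one_casedrop_replicate(
            data10.values, data10.labels, fast_config, data10.n, full,
            "pearson", np.random.SeedSequence(0),
        )
        assert corr == pytest.approx(1.0, abs=1e-9)

    def test_reproducible_given_seed(self, data10, fast_config):
        kwargs = dict(proportions=(0.2, 0.4), B=3, seed=9, config=fast_config)
        a = case_dropping_bootstrap(data10, **kwargs)
        b = case_dropping_bootstrap(data10, **kwargs)
        np.testing.assert_array_equal(a.correlations, b.correlations)
        assert a.correlations.shape == (2, 3)

    def test_grid_leaving_too_few_rows_rejected(self, data10, fast_config):
        with pytest.raises(ValueError, match="50"):
            case_dropping_bootstrap(data10, (0.95,), B=2, seed=0, config=fast_config)

    def test_zero_variance_strength_defines_correlation_zero(self):
        assert _replicate_correlation(np.zeros(5), np.arange(5.0), "pearson") == 0.0
        assert _replicate_correlation(
            np.arange(5.0), np.arange(5.0), "spearman"
        ) == pytest.approx(1.0)

    def test_strongly_coupled_fixture_is_stable_at_half_drop(self, net10):
        """Median strength correlation at 50% dropping stays high for a
        well-determined sparse network (n=5000)."""
        from isingnet.simulate import gibbs_sample

        data = gibbs_sample(net10, 5000, seed=11)
        res = case_dropping_bootstrap(
            data, (0.5,), B=10, seed=5, config=EstimationConfig(n_lambda=30)
        )
        assert np.median(res.correlations) > 0.7


class TestCsCoefficient:
    def grid_result(self, corr: np.ndarray) -> CaseDropResult:
        q = np.linspace(0.1, 0.7, corr.shape[0])
        return CaseDropResult(proportions=q, correlations=corr, seed=0)

    def test_perfect_correlations_give_max_grid_value(self):
        res = self.grid_result(np.ones((7, 10)))
        assert cs_coefficient(res) == pytest.approx(0.7)

    def test_all_zero_correlations_give_zero(self):
        res = self.grid_result(np.zeros((7, 10)))
        assert cs_coefficient(res) == 0.0

    def test_threshold_proportion_identified_exactly(self):
        corr = np.ones((7, 20))
        corr[4:] = 0.5  # proportions 0.5, 0.6, 0.7 fail the 0.7 criterion
        res = self.grid_result(corr)
        assert cs_coefficient(res) == pytest.approx(0.4)

    @given(st.integers(0, 500))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_monotone_in_threshold_and_probability(self, seed):
        rng = np.random.default_rng(seed)
        res = self.grid_result(rng.uniform(-0.2, 1.0, size=(7, 15)))
        for lo, hi in [(0.5, 0.7), (0.7, 0.9)]:
            assert cs_coefficient(res, cor_threshold=hi) <= cs_coefficient(
                res, cor_threshold=lo
            )
        assert cs_coefficient(res, prob=0.99) <= cs_coefficient(res, prob=0.8)
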