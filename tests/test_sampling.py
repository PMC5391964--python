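"""Parameter randomization and the half-functional threshold machinery.

Monte-Carlo expectations asserted here were frozen from large brute-force
runs of the corresponding closed-form quantities (uniform/truncated means,
the median of G/k, the median of a reciprocal uniform).
"""

import numpy as np
import pytest

from racipe import builtin_circuit
from racipe.sampling import (Distribution, SamplingConfig,
                             draw_value, draw_values,
                             estimate_gene_medians, isolated_gene_median,
                             sample_model_parameters,
                             unregulated_level_bounds)
from racipe.topology import CircuitTopology, RegulatoryEdge, Sign


@pytest.fixture(scope="module")
def config():
    return SamplingConfig()


class TestDrawValue:
    def test_uniform_mean(self):
        rng = np.random.default_rng(0)
        draws = draw_values(Distribution.UNIFORM, (1, 100), rng, 1_000_000)
        assert draws.mean() == pytest.approx(50.5, abs=0.1)
        assert draws.min() >= 1 and draws.max() <= 100

    def test_zero_width_interval(self):
        rng = np.random.default_rng(0)
        for dist in Distribution:
            assert draw_value(dist, (3.5, 3.5), rng) == pytest.approx(3.5)

    def test_truncated_gaussian_keeps_midpoint(self):
        # symmetric truncation on [0.1, 1] leaves the mean at 0.55
        rng = np.random.default_rng(1)
        draws = draw_values(Distribution.GAUSSIAN, (0.1, 1.0), rng, 1_000_000)
        assert draws.mean() == pytest.approx(0.55, abs=0.01)
        assert draws.min() >= 0.1 and draws.max() <= 1.0

    def test_exponential_anchored_at_minimum(self):
        rng = np.random.default_rng(2)
        draws = draw_values(Distribution.EXPONENTIAL, (1, 100), rng, 200_000)
        assert draws.min() >= 1 and draws.max() <= 100
        # mean of Exp(width/4) truncated at the max is slightly below 1+24.75
        assert 1 + 0.6 * 24.75 < draws.mean() < 1 + 24.75

    def test_shrink_narrows_uniform_about_midpoint(self):
        rng = np.random.default_rng(3)
        draws = draw_values(Distribution.UNIFORM, (1, 100), rng, 100_000,
                            shrink=0.5)
        assert draws.min() >= 1 + 99 / 4 - 1e-9
        assert draws.max() <= 100 - 99 / 4 + 1e-9
        assert draws.mean() == pytest.approx(50.5, abs=0.3)

    def test_deterministic_given_seed(self):
        a = draw_values(Distribution.GAUSSIAN, (1, 100),
                        np.random.default_rng(11), 1000)
        b = draw_values(Distribution.GAUSSIAN, (1, 100),
                        np.random.default_rng(11), 1000)
        assert np.array_equal(a, b)


class TestIsolatedMedian:
    def test_default_ranges_give_median_near_ninety(self, config):
        # brute-force MC oracle: median of U(1,100)/U(0.1,1) ~ 91-92
        rng = np.random.default_rng(0)
        m0 = isolated_gene_median(
            SamplingConfig(median_estimation_samples=1_000_000), rng)
        assert 80 < m0 < 100

    def test_degenerate_ranges_exact(self):
        cfg = SamplingConfig(G_range=(40.0, 40.0), k_range=(0.8, 0.8))
        m0 = isolated_gene_median(cfg, np.random.default_rng(0))
        assert m0 == pytest.approx(50.0)

    def test_seeded_reproducibility(self, config):
        vals = [isolated_gene_median(config, np.random.default_rng(5))
                for _ in range(2)]
        assert vals[0] == vals[1]

    def test_level_ratio_bound_is_thousand(self, config):
        lo, hi = unregulated_level_bounds(config)
        assert hi / lo == pytest.approx(1000.0)


class TestGeneMedians:
    def test_isolated_gene_inherits_m0(self, config):
        topo = CircuitTopology(["X"])
        med = estimate_gene_medians(topo, config, np.random.default_rng(0))
        assert med.M[0] == med.M0

    def test_inhibition_lowers_the_median(self, config):
        topo = CircuitTopology(["R", "T"])
        topo.add_edge(RegulatoryEdge("R", "T", Sign.INHIBITION))
        med = estimate_gene_medians(topo, config, np.random.default_rng(0))
        assert med.of("T") < med.M0
        assert med.of("R") == med.M0

    def test_activation_raises_nothing_above_max_production(self, config):
        # an activated gene's median stays below the unregulated maximum
        topo = CircuitTopology(["R", "T"])
        topo.add_edge(RegulatoryEdge("R", "T", Sign.ACTIVATION))
        med = estimate_gene_medians(topo, config, np.random.default_rng(0))
        lo, hi = unregulated_level_bounds(config)
        assert med.of("T") <= hi
        # activation with g = G/lambda pulls typical levels below isolated
        assert med.of("T") < med.M0


class TestModelParameters:
    def test_values_respect_ranges(self, config):
        topo = builtin_circuit("TS1SA")
        med = estimate_gene_medians(topo, config, np.random.default_rng(1))
        rng = np.random.default_rng(2)
        for _ in range(200):
            p = sample_model_parameters(topo, config, med, rng)
            assert np.all((p.G >= 1) & (p.G <= 100))
            assert np.all((p.k >= 0.1) & (p.k <= 1))
            assert np.all((p.n >= 1) & (p.n <= 6))
            for lam, sign in zip(p.lam, p.edge_signs):
                if sign is Sign.ACTIVATION:
                    assert 1 <= lam <= 100
                else:
                    assert 0.01 <= lam <= 1
            for e, (src, _) in enumerate(p.edge_pairs):
                m = med.of(src)
                assert 0.02 * m <= p.x0[e] <= 1.98 * m

    def test_inhibitory_fold_change_median(self, config):
        # 1/lambda ~ U(1,100)  =>  median(lambda) = 1/50.5 ~ 0.0198
        rng = np.random.default_rng(3)
        lams = 1.0 / draw_values(Distribution.UNIFORM, (1, 100), rng,
                                 1_000_000)
        assert np.median(lams) == pytest.approx(1 / 50.5, rel=5e-3)

    def test_activator_basal_identity(self, config):
        topo = CircuitTopology(["R", "T"])
        topo.add_edge(RegulatoryEdge("R", "T", Sign.ACTIVATION))
        med = estimate_gene_medians(topo, config, np.random.default_rng(4))
        p = sample_model_parameters(topo, config, med,
                                    np.random.default_rng(5))
        assert p.g[1] * p.lam[0] == pytest.approx(p.G[1])
        assert p.g[0] == pytest.approx(p.G[0])

    def test_bit_identical_given_seed(self, config):
        topo = builtin_circuit("TS2SA")
        med = estimate_gene_medians(topo, config, np.random.default_rng(6))
        a = sample_model_parameters(topo, config, med,
                                    np.random.default_rng(7))
        b = sample_model_parameters(topo, config, med,
                                    np.random.default_rng(7))
        for attr in ("G", "k", "g", "lam", "n", "x0"):
            assert np.array_equal(getattr(a, attr), getattr(b, attr))


class TestConfigIO:
    def test_round_trip(self, tmp_path):
        cfg = SamplingConfig(distribution=Distribution.EXPONENTIAL,
                             range_shrink=0.25, seed=42)
        path = tmp_path / "sampling.cfg"
        cfg.to_file(path)
        again = SamplingConfig.from_file(path)
        assert again == cfg

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            SamplingConfig(k_range=(1.0, 0.1))
        with pytest.raises(ValueError):
            SamplingConfig(range_shrink=0.3)
        with pytest.raises(ValueError):
            SamplingConfig(n_range=(0, 6))
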