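"""Synthetic-data generators: distributional checks against known truth."""

import numpy as np
import pytest

import stgap
from stgap.graph import constrained_icar_covariance, icar_precision
from stgap.simulate import (
    Hyperparameters,
    SimulationConfig,
    simulate_bym2,
    simulate_exposure_grids,
    simulate_graph,
    simulate_interaction,
    simulate_panel,
    simulate_temporal_trend,
)


class TestSimulateGraph:
    @pytest.mark.parametrize("n,expected_edges", [(9, 12), (4, 4), (6, 7)])
    def test_lattice_edge_counts(self, n, expected_edges):
        g = simulate_graph(n, "lattice", seed=0)
        assert g.n_nodes == n and g.n_edges == expected_edges

    def test_deterministic_per_seed(self):
        a = simulate_graph(20, "random_geometric", seed=4)
        b = simulate_graph(20, "random_geometric", seed=4)
        assert a == b

    def test_geometric_graph_connected(self):
        g = simulate_graph(40, "random_geometric", seed=1)
        assert icar_precision(g).n_components == 1

    def test_zero_nodes_rejected(self):
        with pytest.raises(ValueError):
            simulate_graph(0, "lattice", seed=0)


class TestSimulateBym2:
    def test_pure_unstructured_limit_variance(self):
        """phi=0 gives i.i.d. effects with marginal variance 1/tau_s."""
        g = stgap.build_graph([f"N{i}" for i in range(10_000)], [])
        s, u, v = simulate_bym2(g, tau_s=4.0, phi=0.0, seed=1)
        assert np.allclose(u, 0.0)
        assert s.var() == pytest.approx(0.25, rel=0.05)

    def test_pure_structured_limit_sums_to_zero(self, k3):
        s, u, v = simulate_bym2(k3, tau_s=1.0, phi=1.0, seed=2)
        np.testing.assert_allclose(s, u, atol=1e-12)
        assert abs(u.sum()) < 1e-12

    def test_structured_covariance_matches_pinv_oracle(self, k3):
        """Monte-Carlo covariance of phi=1 draws vs. the scaled pseudo-inverse."""
        rng = np.random.default_rng(8)
        draws = np.array(
            [simulate_bym2(k3, tau_s=1.0, phi=1.0, seed=rng)[0] for _ in range(20_000)]
        )
        expected = constrained_icar_covariance(icar_precision(k3), scaled=True)
        emp = np.cov(draws.T)
        np.testing.assert_allclose(emp, expected, atol=0.03)  # ~3 MC standard errors

    def test_phi_out_of_range(self, k3):
        with pytest.raises(ValueError):
            simulate_bym2(k3, tau_s=1.0, phi=1.5, seed=0)


class TestTemporalTrend:
    def test_degenerate_precision_gives_flat_trend(self):
        theta = simulate_temporal_trend(30, tau_theta=1e12, order=1, seed=0)
        assert np.all(np.abs(theta) < 1e-4)

    def test_sum_to_zero(self):
        theta = simulate_temporal_trend(59, tau_theta=100.0, order=1, seed=3)
        assert abs(theta.sum()) < 1e-10

    def test_increment_variance_matches_precision(self):
        """First differences are i.i.d. with variance 1/tau_theta."""
        rng = np.random.default_rng(4)
        diffs = np.concatenate(
            [
                np.diff(simulate_temporal_trend(4, tau_theta=2.0, order=1, seed=rng))
                for _ in range(5000)
            ]
        )
        assert diffs.var() == pytest.approx(0.5, rel=0.05)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            simulate_temporal_trend(2, tau_theta=1.0, order=2, seed=0)


class TestInteraction:
    def test_degenerate_precision(self):
        d = simulate_interaction(10, 10, tau_delta=1e12, seed=0)
        assert np.all(np.abs(d) < 1e-4)

    def test_centered_and_variance(self):
        d = simulate_interaction(100, 100, tau_delta=5.0, seed=1)
        assert abs(d.mean()) < 1e-14
        assert d.var() == pytest.approx(0.2, rel=0.05)


class TestSimulatePanel:
    def test_noise_free_null_is_constant_intercept(self):
        cfg = SimulationConfig(
            n_countries=9, years=(2000, 2004), alpha=2.5,
            true_beta=(0.0,) * 6,
            true_hyper=Hyperparameters(
                tau_e=1e12, tau_s=1e12, phi=0.5, tau_theta=1e12, tau_delta=1e12
            ),
            seed=0,
        )
        sim = simulate_panel(cfg)
        assert np.all(np.abs(sim.panel.y - 2.5) < 1e-4)

    def test_truth_reconstructs_outcome(self):
        cfg = SimulationConfig(
            n_countries=12, years=(2000, 2009), seed=5,
            true_hyper=Hyperparameters(tau_e=1e12, tau_s=2.0, phi=0.4,
                                       tau_theta=50.0, tau_delta=30.0),
        )
        sim = simulate_panel(cfg)
        t = sim.truth
        mu = (
            t["alpha"] + t["s"][:, None] + t["theta"][None, :] + t["delta"]
            + np.einsum("itk,ik->it", np.log(sim.panel.X), t["beta_matrix"])
        )
        assert np.all(np.abs(sim.panel.y - mu) < 1e-4)

    def test_bit_identical_under_same_seed(self):
        cfg = SimulationConfig(n_countries=8, years=(2000, 2005), seed=9)
        a, b = simulate_panel(cfg), simulate_panel(cfg)
        np.testing.assert_array_equal(a.panel.y, b.panel.y)
        np.testing.assert_array_equal(a.panel.X, b.panel.X)
        assert a.graph == b.graph

    def test_covariates_strictly_positive(self):
        sim = simulate_panel(SimulationConfig(n_countries=10, years=(2000, 2004), seed=2))
        assert np.all(sim.panel.X > 0)

    def test_region_betas_override(self):
        cfg = SimulationConfig(
            n_countries=10, years=(2000, 2004), region_count=2, seed=1,
            region_betas={"Africa": (0.2, 0.3), "Americas": (-0.3, 0.1)},
        )
        sim = simulate_panel(cfg)
        bm = sim.truth["beta_matrix"]
        africa = sim.panel.region == "Africa"
        assert np.all(bm[africa, 0] == 0.2) and np.all(bm[~africa, 0] == -0.3)
        # confounders stay global
        assert np.ptp(bm[:, 2]) == 0

    def test_unknown_region_override_rejected(self):
        cfg_kwargs = dict(n_countries=10, years=(2000, 2004), region_count=2, seed=1)
        with pytest.raises(ValueError, match="unknown region"):
            simulate_panel(
                SimulationConfig(region_betas={"Atlantis": (0.1, 0.1)}, **cfg_kwargs)
            )

    def test_missing_rate_applies_to_outcome(self):
        cfg = SimulationConfig(
            n_countries=20, years=(2000, 2009), missing_rate=0.3, seed=4
        )
        frac = np.isnan(simulate_panel(cfg).panel.y).mean()
        assert 0.2 < frac < 0.4


class TestExposureGrids:
    def test_single_zone(self):
        pm, pop, zones = simulate_exposure_grids(1, (2, 2), seed=0)
        assert pm.shape == pop.shape == zones.shape == (2, 2)
        assert np.all(zones == 0)

    def test_deterministic_per_seed(self):
        a = simulate_exposure_grids(3, (5, 5), seed=7)
        b = simulate_exposure_grids(3, (5, 5), seed=7)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_zone_partition_conserves_population(self):
        pm, pop, zones = simulate_exposure_grids(4, (6, 6), seed=1)
        per_zone = [pop[zones == z].sum() for z in range(4)]
        assert sum(per_zone) == pop.sum()
        assert all((zones == z).sum() >= 1 for z in range(4))

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            simulate_exposure_grids(5, (2, 2), seed=0)
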