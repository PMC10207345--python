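"""Spatiotemporal model assembly, MCMC correctness, posterior operations."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.stats import theilslopes

import stgap
from stgap.model import ModelSpec, Priors, build_model, fit_mcmc
from stgap.posterior import (
    combined_spatial_effect,
    local_temporal_trend,
    overall_temporal_trend,
    posterior_summary,
)

from conftest import make_panel


def degenerate_intercept_fit(n, tau_e, n_iter, seed_y=7, seed_fit=3):
    """Intercept-only model with flat prior and known error precision."""
    rng = np.random.default_rng(seed_y)
    y = np.column_stack([rng.normal(2.0, 0.5, size=n)] + [np.full(n, np.nan)] * 2)
    panel = make_panel(n=n, T=3, y=y, X=np.full((n, 3, 6), np.nan))
    graph = stgap.build_graph(panel.country_ids, [])
    spec = ModelSpec(
        variant="M0s", include_spatial=False, include_trend=False,
        include_interaction=False, fixed_tau_e=tau_e,
        priors=Priors(alpha_sd=float("inf")),
    )
    state = build_model(panel, graph, spec)
    fit = fit_mcmc(state, n_iter=n_iter + 200, n_warmup=200, n_chains=1, seed=seed_fit)
    return fit, y[:, 0]


class TestBuildModel:
    def test_m0s_latent_dimension(self):
        panel = make_panel(n=4, T=3)
        graph = stgap.simulate_graph(4, "lattice", 0)
        graph = stgap.build_graph(panel.country_ids,
                                  [(panel.country_ids[i], panel.country_ids[j])
                                   for i, j in graph.edges])
        state = build_model(panel, graph, ModelSpec(variant="M0s"))
        assert state.latent_dim == 1 + 2 * 4 + 3 + 12

    def test_m2s_region_coefficient_count(self):
        sim = stgap.simulate_panel(
            stgap.SimulationConfig(n_countries=12, years=(2000, 2004),
                                   region_count=6, seed=0)
        )
        state = build_model(sim.panel, sim.graph, ModelSpec(variant="M2s"))
        assert len(state.beta_names) == 2 * 6 + 4
        assert sum("pwpm25" in b for b in state.beta_names) == 6

    def test_m2s_requires_regions(self):
        panel = make_panel(n=4, T=5)
        graph = stgap.build_graph(panel.country_ids, [])
        with pytest.raises(ValueError, match="region"):
            build_model(panel, graph, ModelSpec(variant="M2s"))

    def test_zero_covariate_error_names_cell(self):
        with pytest.raises(ValueError, match=r"urbanpop.*C001.*2001|C001.*2001.*urbanpop"):
            X = np.ones((3, 3, 6))
            X[1, 1, 1] = 0.0
            make_panel(n=3, T=3, X=X, years_start=2000)

    def test_mismatched_country_sets_rejected(self):
        panel = make_panel(n=3, T=3)
        graph = stgap.build_graph(["X", "Y", "Z"], [])
        with pytest.raises(ValueError, match="country sets differ"):
            build_model(panel, graph, ModelSpec(variant="M0s"))

    def test_graph_realigned_to_panel_order(self):
        panel = make_panel(n=3, T=3)
        ids = list(panel.country_ids)
        graph = stgap.build_graph(ids[::-1], [(ids[0], ids[1])])
        state = build_model(panel, graph, ModelSpec(variant="M0s"))
        assert tuple(state.graph.node_ids) == panel.country_ids


class TestConjugateOracle:
    def test_intercept_posterior_matches_closed_form(self):
        """Flat-prior intercept with known precision: Normal(ybar, 1/(n tau))."""
        n, tau_e = 20, 4.0
        fit, y = degenerate_intercept_fit(n, tau_e, n_iter=8000)
        draws = fit.alpha
        mcse = draws.std() / math.sqrt(draws.size)
        assert abs(draws.mean() - y.mean()) < 3 * mcse
        assert draws.var() == pytest.approx(1.0 / (n * tau_e), rel=0.10)


class TestSampler:
    def test_same_seed_reproduces_draws(self):
        sim = stgap.simulate_panel(
            stgap.SimulationConfig(n_countries=9, years=(2000, 2007), seed=3)
        )
        state = build_model(sim.panel, sim.graph, ModelSpec(variant="M1s"))
        a = fit_mcmc(state, n_iter=300, n_warmup=100, n_chains=2, seed=11)
        b = fit_mcmc(state, n_iter=300, n_warmup=100, n_chains=2, seed=11)
        np.testing.assert_array_equal(a.alpha, b.alpha)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.hypers["tau_e"], b.hypers["tau_e"])
        np.testing.assert_array_equal(a.pointwise_loglik, b.pointwise_loglik)

    def test_invalid_iteration_counts(self, recovery_sim):
        state = build_model(recovery_sim.panel, recovery_sim.graph, ModelSpec())
        with pytest.raises(ValueError):
            fit_mcmc(state, n_iter=100, n_warmup=100)

    def test_constraints_hold_exactly(self, recovery_fit):
        """Sum-to-zero projections applied each sweep hold to 1e-10."""
        _, fit = recovery_fit
        assert np.abs(fit.u.sum(axis=1)).max() < 1e-10
        assert np.abs(fit.theta.sum(axis=1)).max() < 1e-10
        assert np.abs(fit.delta.sum(axis=(1, 2))).max() < 1e-10

    def test_missing_outcomes_are_handled(self):
        sim = stgap.simulate_panel(
            stgap.SimulationConfig(n_countries=9, years=(2000, 2009),
                                   missing_rate=0.25, seed=6)
        )
        state = build_model(sim.panel, sim.graph, ModelSpec(variant="M1s"))
        assert state.n_obs < 90
        fit = fit_mcmc(state, n_iter=300, n_warmup=100, n_chains=1, seed=2)
        assert np.isfinite(fit.pointwise_loglik).all()

    def test_beta_recovery_on_structured_panel(self, recovery_fit):
        sim, fit = recovery_fit
        truth = sim.truth["beta"]
        z = (fit.beta.mean(0) - truth) / fit.beta.std(0)
        assert np.all(np.abs(z) < 4)

    def test_phi_recovery_direction(self):
        """Strong-vs-weak spatial mixing is ordered in the posterior."""
        wins = 0
        n_pairs = 10
        for k in range(n_pairs):
            means = {}
            for phi in (0.1, 0.9):
                cfg = stgap.SimulationConfig(
                    n_countries=20, years=(2000, 2009), seed=100 + k,
                    true_hyper=stgap.Hyperparameters(
                        tau_e=400.0, tau_s=1.0, phi=phi,
                        tau_theta=1e4, tau_delta=400.0),
                )
                sim = stgap.simulate_panel(cfg)
                state = build_model(sim.panel, sim.graph, ModelSpec(variant="M0s"))
                fit = fit_mcmc(state, n_iter=800, n_warmup=300, n_chains=1,
                               seed=200 + k)
                means[phi] = float(fit.hypers["phi"].mean())
            wins += means[0.9] > means[0.1]
        assert wins >= 9

    def test_sigma2_decreases_with_error_precision_truth(self):
        """Posterior error variance tracks the true noise level monotonically."""
        estimates = []
        for tau_e in (50.0, 200.0, 800.0):
            cfg = stgap.SimulationConfig(
                n_countries=16, years=(2000, 2011), seed=5,
                true_hyper=stgap.Hyperparameters(
                    tau_e=tau_e, tau_s=4.0, phi=0.5, tau_theta=1e4,
                    tau_delta=200.0),
            )
            sim = stgap.simulate_panel(cfg)
            state = build_model(sim.panel, sim.graph, ModelSpec(variant="M0s"))
            fit = fit_mcmc(state, n_iter=700, n_warmup=250, n_chains=1, seed=8)
            estimates.append(float((1.0 / fit.hypers["tau_e"]).mean()))
        assert estimates[0] > estimates[1] > estimates[2]


class TestPosteriorSummary:
    def test_constant_draws_collapse(self, recovery_fit):
        _, fit = recovery_fit
        fixed = dataclasses.replace(fit, alpha=np.full(fit.n_draws, 3.14))
        row = posterior_summary(fixed, ["alpha"]).iloc[0]
        assert row["mean"] == row["q2.5"] == row["q97.5"] == pytest.approx(3.14)

    def test_uniform_grid_mean(self, recovery_fit):
        _, fit = recovery_fit
        fixed = dataclasses.replace(fit, alpha=np.arange(1.0, 101.0))
        assert posterior_summary(fixed, ["alpha"]).iloc[0]["mean"] == pytest.approx(50.5)

    def test_positive_interval_flagged_significant(self, recovery_fit):
        _, fit = recovery_fit
        fixed = dataclasses.replace(fit, alpha=np.linspace(0.019, 0.048, fit.n_draws))
        row = posterior_summary(fixed, ["alpha"]).iloc[0]
        assert bool(row["significant"])
        assert row["q2.5"] > 0

    def test_unknown_quantity_rejected(self, recovery_fit):
        _, fit = recovery_fit
        with pytest.raises(ValueError, match="unknown quantities"):
            posterior_summary(fit, ["beta[nonexistent]"])

    def test_interval_order(self, recovery_fit):
        _, fit = recovery_fit
        table = posterior_summary(fit)
        assert (table["q2.5"] <= table["mean"] + 1e-12).all()
        assert (table["mean"] <= table["q97.5"] + 1e-12).all()


class TestDecompositions:
    def test_combined_effect_consistent_with_draws(self, recovery_fit):
        sim, fit = recovery_fit
        year = int(sim.panel.years[3])
        table = combined_spatial_effect(fit, year)
        expected = (
            fit.s.mean(0) + fit.theta[:, 3].mean() + fit.delta[:, :, 3].mean(0)
        )
        np.testing.assert_allclose(table["mean"].to_numpy(), expected, atol=1e-12)

    def test_combined_effect_recovers_truth(self, recovery_fit):
        sim, fit = recovery_fit
        t = 5
        truth = (
            sim.truth["s"] + sim.truth["theta"][t] + sim.truth["delta"][:, t]
        )
        table = combined_spatial_effect(fit, int(sim.panel.years[t]))
        total = fit.s + fit.theta[:, [t]] + fit.delta[:, :, t]
        z = (table["mean"].to_numpy() - truth) / total.std(axis=0)
        assert np.mean(np.abs(z) < 3) >= 0.85

    def test_year_outside_range_rejected(self, recovery_fit):
        _, fit = recovery_fit
        with pytest.raises(ValueError, match="outside the panel range"):
            combined_spatial_effect(fit, 1900)

    def test_overall_trend_centered_and_recovers_truth(self, recovery_fit):
        sim, fit = recovery_fit
        table = overall_temporal_trend(fit)
        assert abs(table["mean"].sum()) < 1e-10
        z = (table["mean"].to_numpy() - sim.truth["theta"]) / fit.theta.std(0)
        assert np.mean(np.abs(z) < 3) >= 0.9

    def test_unknown_country_rejected(self, recovery_fit):
        _, fit = recovery_fit
        with pytest.raises(ValueError, match="unknown country"):
            local_temporal_trend(fit, "Atlantis")

    def test_injected_country_slope_sign_recovered(self):
        """A country-specific deviation trend is picked up with the right sign."""
        correct = 0
        n_rep = 20
        for k in range(n_rep):
            cfg = stgap.SimulationConfig(
                n_countries=16, years=(2000, 2011), seed=300 + k,
                true_hyper=stgap.Hyperparameters(
                    tau_e=150.0, tau_s=5.0, phi=0.5, tau_theta=2e4,
                    tau_delta=180.0),
            )
            sim = stgap.simulate_panel(cfg)
            slope = 0.05 if k % 2 == 0 else -0.05
            tt = np.arange(sim.panel.n_years, dtype=float)
            sim.panel.y[0] = sim.panel.y[0] + slope * (tt - tt.mean())
            state = build_model(sim.panel, sim.graph, ModelSpec(variant="M0s"))
            fit = fit_mcmc(state, n_iter=600, n_warmup=200, n_chains=1, seed=400 + k)
            local = local_temporal_trend(fit, sim.panel.country_ids[0])
            overall = overall_temporal_trend(fit)
            dev = local["mean"].to_numpy() - overall["mean"].to_numpy()
            est = theilslopes(dev, sim.panel.years).slope
            correct += (est > 0) == (slope > 0)
        assert correct >= 19

    def test_band_width_shrinks_with_interaction_precision(self):
        """Less interaction variance in truth narrows local-trend bands."""
        widths = {}
        for tau_delta in (20.0, 2000.0):
            cfg = stgap.SimulationConfig(
                n_countries=16, years=(2000, 2011), seed=9,
                true_hyper=stgap.Hyperparameters(
                    tau_e=400.0, tau_s=4.0, phi=0.5, tau_theta=1e4,
                    tau_delta=tau_delta),
            )
            sim = stgap.simulate_panel(cfg)
            state = build_model(sim.panel, sim.graph, ModelSpec(variant="M0s"))
            fit = fit_mcmc(state, n_iter=700, n_warmup=250, n_chains=1, seed=10)
            local = local_temporal_trend(fit, sim.panel.country_ids[0])
            widths[tau_delta] = float((local["q97.5"] - local["q2.5"]).mean())
        assert widths[2000.0] < widths[20.0]
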