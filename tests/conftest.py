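"""Shared fixtures: small graphs, panels, and one reusable fitted model."""

import numpy as np
import pytest

import stgap
from stgap.model import ModelSpec, build_model, fit_mcmc
from stgap.panel import COVARIATES, PanelData


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def path3():
    return stgap.build_graph(["A", "B", "C"], [("A", "B"), ("B", "C")])


@pytest.fixture
def k3():
    return stgap.build_graph(["A", "B", "C"], [("A", "B"), ("B", "C"), ("A", "C")])


def make_panel(n=4, T=3, y=None, X=None, region=None, years_start=2000):
    """Minimal valid panel with constant covariates unless overridden."""
    years = np.arange(years_start, years_start + T)
    if y is None:
        y = np.full((n, T), 5.0)
    if X is None:
        X = np.ones((n, T, len(COVARIATES)))
    cids = [f"C{i:03d}" for i in range(n)]
    return PanelData(country_ids=cids, years=years, y=y, X=X, region=region)


@pytest.fixture
def recovery_sim():
    """Simulated panel with clearly visible spatial/temporal structure."""
    cfg = stgap.SimulationConfig(
        n_countries=25,
        years=(2001, 2012),
        seed=42,
        true_hyper=stgap.Hyperparameters(
            tau_e=400.0, tau_s=4.0, phi=0.6, tau_theta=500.0, tau_delta=100.0
        ),
    )
    return stgap.simulate_panel(cfg)


@pytest.fixture(scope="session")
def recovery_fit():
    """One M1s fit on a structured simulated panel, shared across tests."""
    cfg = stgap.SimulationConfig(
        n_countries=25,
        years=(2001, 2012),
        seed=42,
        true_hyper=stgap.Hyperparameters(
            tau_e=400.0, tau_s=4.0, phi=0.6, tau_theta=500.0, tau_delta=100.0
        ),
    )
    sim = stgap.simulate_panel(cfg)
    state = build_model(sim.panel, sim.graph, ModelSpec(variant="M1s"))
    fit = fit_mcmc(state, n_iter=1500, n_warmup=500, n_chains=2, seed=7)
    return sim, fit
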