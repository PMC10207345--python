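"""Simulation studies validating the modeling stack end to end.

Each experiment generates data with known truth, runs the package's own
fitting/scoring code, and returns the summary quantities a reviewer would
check: oracle agreement for the conjugate special case, fixed-effect
recovery and credible-interval coverage, region-specific sign recovery,
WAIC model-preference rates, and trend-taxonomy accuracy.  These drive the
analysis scripts, the acceptance checks, and the test suite.
"""

from __future__ import annotations

import math

import numpy as np

from .compare import compute_waic
from .graph import build_graph
from .model import ModelSpec, Priors, build_model, fit_mcmc
from .panel import COVARIATES, PanelData
from .simulate import Hyperparameters, SimulationConfig, simulate_panel
from .trends import classify_trend

__all__ = [
    "TABLE_HYPERS",
    "conjugate_intercept_check",
    "beta_recovery_experiment",
    "coverage_experiment",
    "region_sign_recovery",
    "waic_preference",
    "trend_taxonomy_accuracy",
]

#: hyperparameter truth used across recovery experiments (gender-gap scale)
TABLE_HYPERS = Hyperparameters(
    tau_e=150.0, tau_s=5.0, phi=0.5, tau_theta=2e4, tau_delta=180.0
)


def conjugate_intercept_check(n=50, tau_e=4.0, n_draws=20_000, seed=0):
    """Degenerate no-random-effects model vs. its closed-form posterior.

    With a flat prior on the intercept and known error precision, the
    posterior is Normal(ybar, 1/(n tau_e)) exactly.  Returns the
    standardized mean error (in Monte-Carlo SEs) and the sampled/exact
    variance ratio.
    """
    rng = np.random.default_rng(seed)
    y_col = rng.normal(2.0, 1.0 / math.sqrt(tau_e), size=n)
    y = np.column_stack([y_col] + [np.full(n, np.nan)] * 2)
    panel = PanelData(
        country_ids=[f"C{i:03d}" for i in range(n)],
        years=np.arange(2000, 2003),
        y=y,
        X=np.full((n, 3, len(COVARIATES)), np.nan),
    )
    graph = build_graph(panel.country_ids, [])
    spec = ModelSpec(
        variant="M0s", include_spatial=False, include_trend=False,
        include_interaction=False, fixed_tau_e=tau_e,
        priors=Priors(alpha_sd=float("inf")),
    )
    state = build_model(panel, graph, spec)
    fit = fit_mcmc(state, n_iter=n_draws + 500, n_warmup=500, n_chains=1, seed=seed)
    draws = fit.alpha
    exact_mean = y_col.mean()
    exact_var = 1.0 / (n * tau_e)
    mcse = draws.std() / math.sqrt(draws.size)
    return {
        "z_mean": float((draws.mean() - exact_mean) / mcse),
        "var_ratio": float(draws.var() / exact_var),
        "n": n,
        "n_draws": int(draws.size),
    }


def _default_config(n_countries, n_years, seed, **overrides):
    kwargs = dict(
        n_countries=n_countries,
        years=(2018 - n_years + 1, 2018),
        true_hyper=TABLE_HYPERS,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def beta_recovery_experiment(
    n_countries=60, n_years=30, seed=0,
    n_iter=2500, n_warmup=1000, n_chains=2,
):
    """Fit the global-coefficient model on one simulated panel.

    Returns per-coefficient standardized errors (posterior mean minus
    truth, in posterior SDs) and their maximum absolute value.
    """
    sim = simulate_panel(_default_config(n_countries, n_years, seed))
    state = build_model(sim.panel, sim.graph, ModelSpec(variant="M1s"))
    fit = fit_mcmc(state, n_iter=n_iter, n_warmup=n_warmup,
                   n_chains=n_chains, seed=seed + 1)
    z = (fit.beta.mean(0) - sim.truth["beta"]) / fit.beta.std(0)
    return {
        "z_scores": dict(zip(COVARIATES, map(float, z))),
        "max_abs_z": float(np.abs(z).max()),
        "n_obs": state.n_obs,
        "fit": fit,
        "sim": sim,
    }


def coverage_experiment(
    n_panels=50, n_countries=30, n_years=20, seed=0,
    n_iter=1000, n_warmup=400,
):
    """Empirical 95% credible-interval coverage of the six coefficients.

    Each replicate simulates a fresh panel under the same truth, fits the
    global-coefficient model, and records whether each equal-tailed 95%
    interval covers the true coefficient.
    """
    covered = np.zeros(len(COVARIATES))
    for k in range(n_panels):
        sim = simulate_panel(_default_config(n_countries, n_years, seed + 1000 + k))
        state = build_model(sim.panel, sim.graph, ModelSpec(variant="M1s"))
        fit = fit_mcmc(state, n_iter=n_iter, n_warmup=n_warmup,
                       n_chains=1, seed=seed + 2000 + k)
        lo, hi = np.quantile(fit.beta, [0.025, 0.975], axis=0)
        covered += (lo <= sim.truth["beta"]) & (sim.truth["beta"] <= hi)
    coverage = covered / n_panels
    return {
        "coverage": dict(zip(COVARIATES, map(float, coverage))),
        "min_coverage": float(coverage.min()),
        "max_coverage": float(coverage.max()),
        "n_panels": n_panels,
    }


def region_sign_recovery(
    n_reps=20, n_countries=30, n_years=15, seed=0,
    beta_pm=(0.2, -0.3), n_iter=800, n_warmup=300,
):
    """Opposite-sign regional exposure coefficients under the M2s model.

    Two regions get pwPM2.5 coefficients of opposite sign; a replicate
    counts as a success when both posterior means have the right sign.
    Returns the success fraction.
    """
    hits = 0
    for k in range(n_reps):
        cfg = _default_config(
            n_countries, n_years, seed + 3000 + k,
            region_count=2,
            region_betas={
                "Africa": (beta_pm[0], 0.251),
                "Americas": (beta_pm[1], 0.251),
            },
        )
        sim = simulate_panel(cfg)
        state = build_model(sim.panel, sim.graph, ModelSpec(variant="M2s"))
        fit = fit_mcmc(state, n_iter=n_iter, n_warmup=n_warmup,
                       n_chains=1, seed=seed + 4000 + k)
        means = dict(zip(state.beta_names, fit.beta.mean(0)))
        ok = (
            np.sign(means["beta[pwpm25|Africa]"]) == np.sign(beta_pm[0])
            and np.sign(means["beta[pwpm25|Americas]"]) == np.sign(beta_pm[1])
        )
        hits += ok
    return {"success_rate": hits / n_reps, "n_reps": n_reps}


def waic_preference(
    kind, n_reps=20, n_countries=20, n_years=12, seed=0,
    n_iter=700, n_warmup=250,
):
    """How often WAIC prefers the richer (correct) model.

    ``kind="covariates"``: panels with real covariate effects, comparing
    the covariate model against the no-covariate baseline.
    ``kind="spatial"``: panels with strong spatial structure (small tau_s)
    and no covariate effects, comparing the BYM2 model against the same
    model with the spatial term removed.
    """
    if kind not in ("covariates", "spatial"):
        raise ValueError("kind must be 'covariates' or 'spatial'")
    wins = 0
    for k in range(n_reps):
        if kind == "covariates":
            cfg = _default_config(n_countries, n_years, seed + 5000 + k)
            specs = (ModelSpec(variant="M1s"), ModelSpec(variant="M0s"))
        else:
            cfg = _default_config(
                n_countries, n_years, seed + 6000 + k,
                true_beta=(0.0,) * 6,
                true_hyper=Hyperparameters(
                    tau_e=150.0, tau_s=1.0, phi=0.9, tau_theta=2e4,
                    tau_delta=180.0,
                ),
            )
            specs = (
                ModelSpec(variant="M0s", include_spatial=True),
                ModelSpec(variant="M0s", include_spatial=False),
            )
        sim = simulate_panel(cfg)
        waics = []
        for j, spec in enumerate(specs):
            state = build_model(sim.panel, sim.graph, spec)
            fit = fit_mcmc(state, n_iter=n_iter, n_warmup=n_warmup,
                           n_chains=1, seed=seed + 7000 + 2 * k + j)
            waics.append(compute_waic(fit).waic)
        wins += waics[0] < waics[1]
    return {"win_rate": wins / n_reps, "n_reps": n_reps}


def trend_taxonomy_accuracy(
    n_noisy=200, noise_sd=0.1, amplitude=4.0, n_years=30, seed=0
):
    """Label accuracy on synthetic monotone and tent-shaped trajectories.

    Noise-free monotone and tent series must classify perfectly; noisy
    tents (Gaussian noise on a tent of the given amplitude) report an
    accuracy over replicates.
    """
    years = np.arange(1989, 1989 + n_years)
    tt = np.arange(n_years, dtype=float)
    half = (n_years - 1) / 2.0
    tent = amplitude * (1.0 - np.abs(tt - half) / half)
    clean_ok = (
        classify_trend(0.1 * tt + 1.0, years).label == "increasing"
        and classify_trend(-0.1 * tt + 5.0, years).label == "decreasing"
        and classify_trend(tent, years).label == "peak"
    )
    rng = np.random.default_rng(seed)
    hits = sum(
        classify_trend(tent + rng.normal(0.0, noise_sd, n_years), years).label
        == "peak"
        for _ in range(n_noisy)
    )
    return {
        "noise_free_accuracy": 1.0 if clean_ok else 0.0,
        "noisy_accuracy": hits / n_noisy,
        "n_noisy": n_noisy,
    }
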