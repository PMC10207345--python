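"""Posterior summaries and spatiotemporal decompositions of a fitted model.

Summaries are posterior means with equal-tailed 95% credible intervals
(linear-interpolation quantiles); a quantity is flagged significant when
its interval excludes zero.  The decomposition operations reproduce the
quantities a spatiotemporal analysis reports: the combined spatial effect
``s_i + theta_t + delta_it`` of each country at a chosen year, the overall
temporal trend ``theta_t``, and country-specific local trends
``theta_t + delta_it``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import FitResult, HYPER_NAMES

__all__ = [
    "posterior_summary",
    "combined_spatial_effect",
    "local_temporal_trend",
    "overall_temporal_trend",
]


def _summarize(draws: np.ndarray, names) -> pd.DataFrame:
    """Mean / 2.5% / 97.5% / significance table for columns of ``draws``."""
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    mean = draws.mean(axis=0)
    lo, hi = np.quantile(draws, [0.025, 0.975], axis=0, method="linear")
    sig = (lo > 0) | (hi < 0)
    return pd.DataFrame(
        {"quantity": list(names), "mean": mean, "q2.5": lo, "q97.5": hi,
         "significant": sig}
    )


def _named_draws(fit: FitResult) -> dict:
    state = fit.state
    named = {"alpha": fit.alpha}
    for j, name in enumerate(fit.beta_names):
        named[name] = fit.beta[:, j]
    for name in HYPER_NAMES:
        if name == "tau_e" and state.spec.fixed_tau_e is not None:
            continue
        if not state.spec.include_spatial and name in ("tau_s", "phi"):
            continue
        if not state.spec.include_trend and name == "tau_theta":
            continue
        if not state.spec.include_interaction and name == "tau_delta":
            continue
        named[name] = fit.hypers[name]
    if "tau_e" in named:
        named["sigma2_e"] = 1.0 / fit.hypers["tau_e"]
    if state.spec.include_spatial:
        for i, cid in enumerate(state.panel.country_ids):
            named[f"s[{cid}]"] = fit.s[:, i]
    if state.spec.include_trend:
        for j, yr in enumerate(state.panel.years):
            named[f"theta[{int(yr)}]"] = fit.theta[:, j]
    return named


def posterior_summary(fit: FitResult, quantities=None) -> pd.DataFrame:
    """Posterior mean and 95% credible interval per requested quantity.

    ``quantities`` defaults to the intercept, fixed effects, and
    hyperparameters.  Per-country spatial effects (``s[<id>]``) and
    per-year trend values (``theta[<year>]``) can be requested by name.
    """
    named = _named_draws(fit)
    if quantities is None:
        quantities = ["alpha", *fit.beta_names]
        quantities += [q for q in (*HYPER_NAMES, "sigma2_e") if q in named]
    unknown = [q for q in quantities if q not in named]
    if unknown:
        raise ValueError(f"unknown quantities: {unknown}")
    draws = np.column_stack([named[q] for q in quantities])
    return _summarize(draws, quantities)


def combined_spatial_effect(fit: FitResult, year: int) -> pd.DataFrame:
    """Per-country summary of ``s_i + theta_t + delta_it`` at one year.

    Positive values mean the country sits above the overall level in that
    year.  Requires the spatial term; trend and interaction contribute when
    present in the fitted variant.
    """
    state = fit.state
    yindex = state.panel.year_index()
    if int(year) not in yindex:
        raise ValueError(
            f"year {year} outside the panel range "
            f"[{int(state.panel.years[0])}, {int(state.panel.years[-1])}]"
        )
    t = yindex[int(year)]
    n = state.n
    total = np.zeros((fit.n_draws, n))
    if state.spec.include_spatial:
        total += fit.s
    if state.spec.include_trend:
        total += fit.theta[:, [t]]
    if state.spec.include_interaction:
        total += fit.delta[:, :, t]
    out = _summarize(total, state.panel.country_ids)
    return out.rename(columns={"quantity": "country_id"})


def local_temporal_trend(fit: FitResult, country) -> pd.DataFrame:
    """Per-year summary of the country-specific trend ``theta_t + delta_it``."""
    state = fit.state
    cindex = state.panel.country_index()
    if country not in cindex:
        raise ValueError(f"unknown country {country!r}")
    i = cindex[country]
    total = np.zeros((fit.n_draws, state.T))
    if state.spec.include_trend:
        total += fit.theta
    if state.spec.include_interaction:
        total += fit.delta[:, i, :]
    out = _summarize(total, [int(y) for y in state.panel.years])
    return out.rename(columns={"quantity": "year"})


def overall_temporal_trend(fit: FitResult) -> pd.DataFrame:
    """Per-year summary of the shared temporal trend ``theta_t``."""
    state = fit.state
    if not state.spec.include_trend:
        raise ValueError("model was fitted without a temporal trend")
    out = _summarize(fit.theta, [int(y) for y in state.panel.years])
    return out.rename(columns={"quantity": "year"})
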