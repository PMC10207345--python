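"""DIC and WAIC model comparison from per-draw pointwise log-likelihoods.

DIC uses the Spiegelhalter plug-in form: ``DIC = Dbar + pD`` with
``pD = Dbar - D(plug-in)``, where the plug-in deviance evaluates the
Gaussian likelihood at the posterior mean of the fitted values and of the
noise precision.  WAIC uses the variance-based effective-parameter count:
``WAIC = -2 * sum_i [lppd_i - var_draws(loglik_i)]`` with the pointwise
log predictive density computed by a stable log-sum-exp.  Smaller is
better for both.

Both criteria are computed on the delta-marginal focus: the cell-level
space-time interaction (one parameter per observation, confounded with
the Gaussian error in the likelihood) is integrated into the noise, so
the criteria depend only on likelihood-identified quantities.  Without
this, the effective-parameter terms are dominated by the prior-driven
tau_e/tau_delta split rather than by model structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .model import FitResult

__all__ = ["FitScore", "compute_dic", "compute_waic", "score_fit", "compare_models"]


@dataclass
class FitScore:
    """Goodness-of-fit scores for one fitted model."""

    model: str
    dic: float = math.nan
    p_d: float = math.nan
    waic: float = math.nan
    p_waic: float = math.nan
    n_obs: int = 0


def _noise_precision_draws(fit) -> np.ndarray:
    """Per-draw precision of the observation predictive density.

    When the fit includes the cell-level interaction, its variance is
    folded into the noise (the pointwise log-likelihoods are recorded on
    the same delta-marginal focus); otherwise this is the error precision.
    """
    tau_e = np.asarray(fit.hypers["tau_e"], dtype=float)
    spec = getattr(getattr(fit, "state", None), "spec", None)
    if spec is not None and spec.include_interaction:
        tau_d = np.asarray(fit.hypers["tau_delta"], dtype=float)
        return tau_e * tau_d / (tau_e + tau_d)
    return tau_e


def _plugin_loglik(fit: FitResult) -> np.ndarray:
    y = fit.state.y_obs
    tau_hat = float(_noise_precision_draws(fit).mean())
    mu_hat = fit.fitted_mean
    return 0.5 * np.log(tau_hat / (2 * np.pi)) - 0.5 * tau_hat * (y - mu_hat) ** 2


def compute_dic(fit: FitResult, model: str = "") -> FitScore:
    """Deviance information criterion with plug-in effective parameters."""
    ll = fit.pointwise_loglik
    if ll.shape[0] < 10:
        raise ValueError(f"need at least 10 posterior draws, got {ll.shape[0]}")
    dbar = float(-2.0 * ll.sum(axis=1).mean())
    dhat = float(-2.0 * _plugin_loglik(fit).sum())
    p_d = dbar - dhat
    return FitScore(model=model, dic=dbar + p_d, p_d=p_d, n_obs=ll.shape[1])


def compute_waic(fit: FitResult, model: str = "") -> FitScore:
    """Widely applicable information criterion (variance-form p_waic)."""
    ll = fit.pointwise_loglik
    if ll.shape[0] < 10:
        raise ValueError(f"need at least 10 posterior draws, got {ll.shape[0]}")
    S = ll.shape[0]
    lppd = logsumexp(ll, axis=0) - math.log(S)
    p_w = ll.var(axis=0, ddof=1)
    waic = float(-2.0 * (lppd - p_w).sum())
    return FitScore(model=model, waic=waic, p_waic=float(p_w.sum()), n_obs=ll.shape[1])


def score_fit(fit: FitResult, model: str = "") -> FitScore:
    """Both criteria for one fit."""
    d = compute_dic(fit, model)
    w = compute_waic(fit, model)
    return FitScore(
        model=model, dic=d.dic, p_d=d.p_d, waic=w.waic, p_waic=w.p_waic, n_obs=d.n_obs
    )


def compare_models(scores) -> pd.DataFrame:
    """Rank fits by WAIC ascending (smaller is better) with deltas.

    All scores must come from fits of the same observations; ties keep the
    input order (stable sort).
    """
    scores = list(scores)
    if len(scores) < 2:
        raise ValueError("need at least two scores to compare")
    n_obs = {s.n_obs for s in scores}
    if len(n_obs) != 1:
        raise ValueError(f"scores computed on different observation counts: {sorted(n_obs)}")
    df = pd.DataFrame(
        [
            {"model": s.model, "dic": s.dic, "p_d": s.p_d, "waic": s.waic,
             "p_waic": s.p_waic, "n_obs": s.n_obs}
            for s in scores
        ]
    )
    df = df.sort_values("waic", kind="stable").reset_index(drop=True)
    df["delta_waic"] = df["waic"] - df["waic"].iloc[0]
    if df["dic"].notna().all():
        df["delta_dic"] = df["dic"] - df["dic"].min()
    return df
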