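"""Posterior-based fit measures.

The pD-substituted fit indices evaluate the frequentist index formulas at
every MCMC iteration, replacing the chi-square statistic T by
D_i^obs - pD and the degrees of freedom by p* - pD, where D_i^obs is the
draw's deviance relative to the saturated model (so the substitution
collapses to the ML quantities for a degenerate posterior), pD is the
effective number of parameters (mean deviance minus deviance at the
posterior means) and p* the number of unique sample moments (180 for 12
items and two groups).

Model selection criteria: a Bayesian analog of the LRT based on deviances
at the EAP estimates, the DIC, and the fully Bayesian WAIC and PSIS-LOO
computed from the pointwise log-likelihood matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .bayes_engine import PosteriorDraws

BAYES_INDEX_MEASURES = ("cfi", "tli", "rmsea", "gh", "mfi")


def effective_p(deviance_series: np.ndarray, d_at_posterior_mean: float) -> float:
    """pD = mean posterior deviance minus deviance at the posterior means."""
    series = np.asarray(deviance_series, float)
    if series.size == 0:
        raise ValueError("empty deviance series")
    return float(series.mean() - d_at_posterior_mean)


@dataclass
class BayesFitSummary:
    """Per-iteration Bayesian fit-index series plus scalar summaries."""

    index_series: dict[str, np.ndarray] = field(repr=False)
    pd_target: float = np.nan
    pd_baseline: float = np.nan
    p_star: int = 0
    n_total: int = 0

    def summary(self) -> pd.DataFrame:
        rows = {}
        for name, series in self.index_series.items():
            rows[name] = {
                "eap": series.mean(),
                "median": np.median(series),
                "q2.5": np.percentile(series, 2.5),
                "q97.5": np.percentile(series, 97.5),
            }
        return pd.DataFrame(rows).T

    def eap(self) -> dict[str, float]:
        return {k: float(v.mean()) for k, v in self.index_series.items()}


def bayes_fit_indices(target_draws: PosteriorDraws,
                      baseline_draws: PosteriorDraws) -> BayesFitSummary:
    """pD-substituted CFI, TLI, RMSEA, GH and MFI distributions.

    Target and baseline must be sampled on the same data with the same
    number of retained draws so the per-iteration substitution is paired.
    """
    if target_draws.n_draws != baseline_draws.n_draws:
        raise ValueError("target and baseline must have equal retained draws")
    if target_draws.moments.sizes != baseline_draws.moments.sizes:
        raise ValueError("target and baseline must be fitted to the same data")
    p = target_draws.spec.n_items
    p_star = 2 * p * (p + 3) // 2
    n_total = target_draws.moments.n_total

    pd_t = effective_p(target_draws.deviance_flat, target_draws.deviance_at_eap())
    pd_b = effective_p(baseline_draws.deviance_flat, baseline_draws.deviance_at_eap())

    t_i = target_draws.d_obs_flat - pd_t
    b_i = baseline_draws.d_obs_flat - pd_b
    df_t = p_star - pd_t
    df_b = p_star - pd_b
    nm1 = n_total - 1

    excess_t = t_i - df_t
    excess_b = b_i - df_b
    denom = np.maximum(np.maximum(excess_t, excess_b), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cfi = np.where(denom > 0, 1.0 - np.maximum(excess_t, 0.0) / denom, 1.0)
    series = {
        "cfi": cfi,
        "tli": (b_i / df_b - t_i / df_t) / (b_i / df_b - 1.0),
        "rmsea": np.sqrt(np.maximum(excess_t, 0.0) / (nm1 * df_t)),
        "gh": p / (p + 2.0 * excess_t / nm1),
        "mfi": np.exp(-0.5 * excess_t / nm1),
    }
    return BayesFitSummary(index_series=series, pd_target=pd_t,
                           pd_baseline=pd_b, p_star=p_star, n_total=n_total)


def bayes_lrt(draws_restricted: PosteriorDraws, draws_free: PosteriorDraws,
              alpha: float = 0.05):
    """Bayesian analog of the LRT: difference of deviances at the EAP
    estimates, compared to the chi-square critical value at ``alpha``.

    Returns (delta_D, delta_df, selected) with selected in
    {"restricted", "free"}.
    """
    ddf = draws_free.spec.n_free - draws_restricted.spec.n_free
    if ddf <= 0:
        raise ValueError("models are not nested in the expected order")
    dd = draws_restricted.deviance_at_eap() - draws_free.deviance_at_eap()
    crit = float(stats.chi2.ppf(1.0 - alpha, ddf))
    return dd, ddf, ("free" if dd > crit else "restricted")


def dic(deviance_at_eap: float, p_d: float) -> float:
    """DIC = D(theta_EAP) + 2 pD."""
    return float(deviance_at_eap + 2.0 * p_d)


def waic(pointwise: np.ndarray):
    """WAIC = -2 lppd + 2 pW from a (draws x subjects) log-likelihood
    matrix; lppd via log-mean-exp per subject, pW as the per-subject
    posterior variance (divisor I-1), both summed over subjects."""
    ll = np.asarray(pointwise, float)
    if not np.isfinite(ll).all():
        raise ValueError("pointwise log-likelihood contains non-finite values")
    n_draws = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(n_draws)))
    p_w = float(np.sum(ll.var(axis=0, ddof=1))) if n_draws > 1 else 0.0
    return -2.0 * lppd + 2.0 * p_w, lppd, p_w


def loo(pointwise: np.ndarray):
    """PSIS leave-one-out cross-validation.

    Importance weights proportional to 1/p(y_j|theta_i), Pareto-smoothed
    and self-normalized; subjects whose Pareto tail index exceeds 0.7 are
    flagged as unreliable.  Returns (LOO, lppd_loo, diagnostics).
    """
    ll = np.asarray(pointwise, float)
    if not np.isfinite(ll).all():
        raise ValueError("pointwise log-likelihood contains non-finite values")
    if ll.shape[0] == 1:
        lppd = float(ll.sum())
        return -2.0 * lppd, lppd, {"pareto_k": np.zeros(ll.shape[1]), "n_flagged": 0}
    log_weights, pareto_k = az.psislw(-ll.T.copy())
    lppd_loo = float(np.sum(logsumexp(log_weights + ll.T, axis=1)))
    k = np.asarray(pareto_k, float)
    return -2.0 * lppd_loo, lppd_loo, {
        "pareto_k": k, "n_flagged": int((k > 0.7).sum()),
    }


def bayes_ic_panel(draws: PosteriorDraws, pointwise: np.ndarray) -> dict[str, float]:
    """Scalar selection criteria for one model: DIC, BIC (at the EAP),
    WAIC and LOO, plus their ingredients."""
    d_eap = draws.deviance_at_eap()
    p_d = effective_p(draws.deviance_flat, d_eap)
    w, lppd, p_w = waic(pointwise)
    l, lppd_loo, diag = loo(pointwise)
    n = draws.moments.n_total
    return {
        "dic": dic(d_eap, p_d),
        "bic": d_eap + draws.spec.n_free * float(np.log(n)),
        "waic": w, "lppd": lppd, "p_waic": p_w,
        "loo": l, "lppd_loo": lppd_loo, "loo_flagged": diag["n_flagged"],
        "p_d": p_d, "deviance_at_eap": d_eap,
        "d_bar": float(draws.deviance_flat.mean()),
    }
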