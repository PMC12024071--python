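"""Frequentist fit measures for invariance-model comparison.

Three families:

* the likelihood-ratio (chi-square difference) test between nested models;
* goodness-of-fit indices computed from the chi-square statistic T of the
  target model and of an independence baseline — CFI, TLI, RMSEA,
  Gamma hat (GH) and the McDonald fit index (MFI);
* information criteria — AIC, BIC and the sample-size-adjusted BIC
  (SaBIC) — computed from the deviance and the free-parameter count.

``n`` in the index and SaBIC formulas is the total sample size across
groups, consistent with T = N * F.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cfa_ml_core import MLFitResult

INDEX_MEASURES = ("cfi", "tli", "rmsea", "gh", "mfi")
IC_MEASURES = ("aic", "bic", "sabic")


@dataclass
class FitMeasurePanel:
    """Named fit-measure values plus provenance (model level, T, df, n)."""

    values: dict[str, float]
    level: str = ""
    t_stat: float = np.nan
    df: int = 0
    n_total: int = 0

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.level)


def lrt_compare(fit_restricted: MLFitResult, fit_free: MLFitResult):
    """Chi-square difference test between two nested fits.

    Returns (delta_D, delta_df, p).  The deviance difference is clipped at
    zero (optimizer noise can produce a tiny negative value).
    """
    ddf = fit_restricted.df - fit_free.df
    if ddf <= 0:
        raise ValueError(
            "models are not nested in the expected order "
            f"(df {fit_restricted.df} vs {fit_free.df})"
        )
    dd = max(fit_restricted.deviance - fit_free.deviance, 0.0)
    p = float(stats.chi2.sf(dd, ddf)) if dd > 0 else 1.0
    return dd, ddf, p


def fit_indices(t_t: float, df_t: int, t_b: float | None, df_b: int | None,
                n_total: int, p: int = 12) -> FitMeasurePanel:
    """Goodness-of-fit indices from target and baseline chi-squares.

        CFI   = 1 - max(T_T - df_T, 0) / max(T_T - df_T, T_B - df_B, 0)
        TLI   = (T_B/df_B - T_T/df_T) / (T_B/df_B - 1)
        RMSEA = sqrt(max(T_T - df_T, 0) / ((n - 1) df_T))
        GH    = p / (p + 2 (T_T - df_T) / (n - 1))
        MFI   = exp(-0.5 (T_T - df_T) / (n - 1))

    When the baseline fit is unavailable the incremental indices (CFI,
    TLI) are omitted and only the absolute indices are returned.
    """
    if df_t <= 0:
        raise ValueError("df_t must be positive")
    if n_total <= 1:
        raise ValueError("n_total must exceed 1")
    excess = t_t - df_t
    nm1 = n_total - 1
    vals = {
        "rmsea": float(np.sqrt(max(excess, 0.0) / (nm1 * df_t))),
        "gh": float(p / (p + 2.0 * excess / nm1)),
        "mfi": float(np.exp(-0.5 * excess / nm1)),
    }
    if t_b is not None and df_b is not None:
        if df_b <= 0:
            raise ValueError("df_b must be positive")
        denom = max(excess, t_b - df_b, 0.0)
        vals["cfi"] = 1.0 - max(excess, 0.0) / denom if denom > 0 else 1.0
        vals["tli"] = float((t_b / df_b - t_t / df_t) / (t_b / df_b - 1.0))
    return FitMeasurePanel(values=vals, t_stat=t_t, df=df_t, n_total=n_total)


def information_criteria(deviance: float, k: int, n_total: int) -> FitMeasurePanel:
    """AIC, BIC and SaBIC from the deviance and free-parameter count.

        AIC   = D + 2k
        BIC   = D + k ln(n)
        SaBIC = D + k ln((n + 2) / 24)
    """
    if k < 0 or n_total <= 0:
        raise ValueError("need k >= 0 and n_total > 0")
    vals = {
        "aic": deviance + 2.0 * k,
        "bic": deviance + k * np.log(n_total),
        "sabic": deviance + k * np.log((n_total + 2.0) / 24.0),
    }
    return FitMeasurePanel(values={m: float(v) for m, v in vals.items()},
                           n_total=n_total)


def panel_from_fits(fit: MLFitResult, fit_baseline: MLFitResult | None = None
                    ) -> FitMeasurePanel:
    """Full measure panel (indices + ICs) for one fitted model."""
    t_b = df_b = None
    if fit_baseline is not None:
        t_b, df_b = fit_baseline.t_stat, fit_baseline.df
    panel = fit_indices(fit.t_stat, fit.df, t_b, df_b, fit.n_total,
                        p=fit.spec.n_items)
    panel.values.update(
        information_criteria(fit.deviance, fit.spec.n_free, fit.n_total).values
    )
    panel.level = fit.spec.level
    return panel


def delta_panel(panel_restricted: FitMeasurePanel,
                panel_free: FitMeasurePanel) -> dict[str, float]:
    """Signed differences oriented so that larger deltas mean the free
    model fits better: value_free - value_restricted for CFI/TLI/GH/MFI,
    restricted - free for RMSEA."""
    deltas = {}
    for m in INDEX_MEASURES:
        if m not in panel_restricted.values or m not in panel_free.values:
            continue
        if m == "rmsea":
            deltas[m] = panel_restricted[m] - panel_free[m]
        else:
            deltas[m] = panel_free[m] - panel_restricted[m]
    return deltas
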