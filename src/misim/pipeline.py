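"""Simulation orchestration: decision rules, replication loops, false/true
positive rates and the factorial ANOVA on fit-value differences.

Per replication the relevant model pair is fitted (configural vs metric
for loading noninvariance, metric vs scalar for intercept noninvariance,
both pairs for invariant data) and each fit measure issues a decision:

* LRT — keep the restricted model if p >= 0.05;
* fit indices — keep the restricted model if the (oriented) delta is
  strictly below its threshold: dCFI < .01, dTLI < .01, dRMSEA < .015,
  dMFI < .02, dGH < .001;
* information criteria — the model with the smaller value wins, exact
  ties favoring the restricted model.

False positive rate: share of replications selecting the free model on
invariant data (binomial acceptance band 0.05 +/- 1.96*sqrt(.05*.95/R));
true positive rate: the same share on noninvariant data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from . import bayes_fit_measures as bfm
from .bayes_engine import (PosteriorDraws, PriorSpec, SamplerSettings,
                           convergence_check, pointwise_loglik, sample_posterior)
from .cfa_ml_core import ModelSpec, fit_ml, model_df, sample_moments
from .ml_fit_measures import panel_from_fits
from .synthetic_data import (PopulationSpec, generate_dataset, make_population,
                             replication_seed)

log = logging.getLogger(__name__)

DELTA_THRESHOLDS = {"cfi": 0.01, "tli": 0.01, "rmsea": 0.015,
                    "mfi": 0.02, "gh": 0.001}
ML_IC_MEASURES = ("aic", "bic", "sabic")
BAYES_IC_MEASURES = ("dic", "bic", "waic", "loo")
LRT_ALPHA = 0.05

# model pair per comparison side: (restricted, free)
PAIRS = {"metric": ("metric", "configural"), "scalar": ("scalar", "metric")}


@dataclass
class ComparisonDecision:
    """Outcome of one measure's model choice in one replication."""

    measure: str
    comparison: str  # metric | scalar  (which invariance stage is tested)
    delta: float
    threshold: float | None
    selected: str  # restricted | free
    rep: int
    condition: str
    n_per_group: int
    lvar_ratio: float
    mean_diff: float
    n_noninv_items: int
    noninv_magnitude: float
    noninv_location: str
    engine: str


def decide(panel_restricted: dict, panel_free: dict, measure: str,
           rules: dict | None = None) -> tuple[float, float | None, str]:
    """Apply one measure's decision rule to a restricted/free panel pair.

    Panels are flat dicts of measure values; for the LRT they must also
    carry ``deviance`` and ``df``.  Returns (delta, threshold, selected).
    """
    rules = rules or DELTA_THRESHOLDS
    if measure == "lrt":
        ddf = panel_restricted["df"] - panel_free["df"]
        if ddf <= 0:
            raise ValueError("LRT requires the restricted model to have larger df")
        dd = max(panel_restricted["deviance"] - panel_free["deviance"], 0.0)
        p = float(stats.chi2.sf(dd, ddf)) if dd > 0 else 1.0
        return dd, None, ("restricted" if p >= LRT_ALPHA else "free")
    if measure in rules:
        if measure == "rmsea":
            delta = panel_restricted[measure] - panel_free[measure]
        else:
            delta = panel_free[measure] - panel_restricted[measure]
        thr = rules[measure]
        return delta, thr, ("restricted" if delta < thr else "free")
    if measure in panel_restricted and measure in panel_free:
        delta = panel_restricted[measure] - panel_free[measure]
        return delta, None, ("restricted" if delta <= 0 else "free")
    raise ValueError(f"unknown measure {measure!r}")


def _sides_for(spec: PopulationSpec) -> list[str]:
    if spec.is_invariant:
        return ["metric", "scalar"]
    return ["metric"] if spec.noninv_location == "loading" else ["scalar"]


def _ml_panels(moments, levels, t_scale, rng):
    fits = {lv: fit_ml(ModelSpec(lv), moments, t_scale=t_scale, rng=rng)
            for lv in levels}
    fits["baseline"] = fit_ml(ModelSpec("baseline"), moments, t_scale=t_scale)
    panels = {}
    for lv in levels:
        panel = panel_from_fits(fits[lv], fits["baseline"])
        panels[lv] = {**panel.values, "deviance": fits[lv].deviance,
                      "df": fits[lv].df, "converged": fits[lv].converged}
    return panels


def _bayes_panels(moments, dataset, levels, priors, settings):
    base = sample_posterior(ModelSpec("baseline"), moments, priors, settings)
    panels = {}
    for k, lv in enumerate(levels):
        # offset each model's sampler seed so chains are not shared
        s = SamplerSettings(settings.chains, settings.warmup, settings.iters,
                            settings.seed + k + 1)
        draws = sample_posterior(ModelSpec(lv), moments, priors, s)
        conv = convergence_check(draws)["converged"]
        idx = bfm.bayes_fit_indices(draws, base).eap()
        ics = bfm.bayes_ic_panel(draws, pointwise_loglik(draws, dataset))
        panels[lv] = {**idx, "dic": ics["dic"], "bic": ics["bic"],
                      "waic": ics["waic"], "loo": ics["loo"],
                      "deviance": ics["deviance_at_eap"],
                      "df": model_df(ModelSpec(lv)),
                      "converged": conv}
    return panels


def run_condition(spec: PopulationSpec, n_reps: int, engine: str = "ml",
                  master_seed: int = 0, condition_index: int = 0,
                  t_scale: str = "N", priors: PriorSpec | None = None,
                  bayes_settings: SamplerSettings | None = None,
                  ) -> list[ComparisonDecision]:
    """Run all replications of one condition and emit every measure's
    decision.  Replications in which either model of a pair fails to
    converge are logged and excluded."""
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    if engine not in ("ml", "bayes"):
        raise ValueError("engine must be 'ml' or 'bayes'")
    if engine == "bayes":
        bayes_settings = bayes_settings or SamplerSettings()
        priors = priors or PriorSpec()

    sides = _sides_for(spec)
    levels = sorted({lv for side in sides for lv in PAIRS[side]})
    ic_measures = ML_IC_MEASURES if engine == "ml" else BAYES_IC_MEASURES
    measures = ("lrt",) + tuple(DELTA_THRESHOLDS) + tuple(ic_measures)

    decisions: list[ComparisonDecision] = []
    for rep in range(n_reps):
        ss = replication_seed(master_seed, condition_index, rep)
        dataset = generate_dataset(spec, ss)
        moments = sample_moments(dataset)
        if np.min([np.diag(S).min() for S in moments.covs]) < 1e-10:
            log.warning("degenerate data in rep %d of %s; excluded", rep, spec.label)
            continue
        if engine == "ml":
            rng = np.random.default_rng(ss.spawn(1)[0])
            panels = _ml_panels(moments, levels, t_scale, rng)
        else:
            s = SamplerSettings(bayes_settings.chains, bayes_settings.warmup,
                                bayes_settings.iters,
                                int(ss.generate_state(1, dtype=np.uint32)[0] >> 2))
            panels = _bayes_panels(moments, dataset, levels, priors, s)
        for side in sides:
            restricted, free = PAIRS[side]
            if not (panels[restricted]["converged"] and panels[free]["converged"]):
                log.warning("nonconvergence in rep %d (%s, %s pair); excluded",
                            rep, spec.label, side)
                continue
            for m in measures:
                delta, thr, sel = decide(panels[restricted], panels[free], m)
                decisions.append(ComparisonDecision(
                    measure=m, comparison=side, delta=float(delta),
                    threshold=thr, selected=sel, rep=rep, condition=spec.label,
                    n_per_group=spec.n_per_group, lvar_ratio=spec.lvar_ratio,
                    mean_diff=spec.mean_diff, n_noninv_items=spec.n_noninv_items,
                    noninv_magnitude=spec.noninv_magnitude,
                    noninv_location=spec.noninv_location, engine=engine,
                ))
    return decisions


def decisions_frame(decisions: list[ComparisonDecision]) -> pd.DataFrame:
    return pd.DataFrame([asdict(d) for d in decisions])


def run_grid(conditions: list[PopulationSpec], n_reps: int, engine: str = "ml",
             master_seed: int = 0, **kwargs) -> pd.DataFrame:
    """Run a list of conditions; condition indices follow list order so a
    single replication can be regenerated from (seed, index, rep)."""
    frames = []
    for idx, spec in enumerate(conditions):
        dec = run_condition(spec, n_reps, engine=engine,
                            master_seed=master_seed, condition_index=idx,
                            **kwargs)
        frames.append(decisions_frame(dec))
    return pd.concat(frames, ignore_index=True)


def rate_table(decisions: pd.DataFrame | list, truth: str,
               nominal: float = 0.05) -> pd.DataFrame:
    """Per condition x comparison x measure selection rates.

    ``truth`` is "invariant" (rates are false positives) or
    "noninvariant" (true positives).  The binomial acceptance band around
    the nominal alpha is attached for FP tables.
    """
    if truth not in ("invariant", "noninvariant"):
        raise ValueError("truth must be 'invariant' or 'noninvariant'")
    df = decisions if isinstance(decisions, pd.DataFrame) else decisions_frame(decisions)
    if df.empty:
        raise ValueError("no decisions to summarize")
    keys = ["condition", "n_per_group", "lvar_ratio", "mean_diff",
            "n_noninv_items", "noninv_magnitude", "noninv_location",
            "comparison", "measure"]
    grp = df.groupby(keys, sort=False)["selected"]
    out = grp.agg(rate=lambda s: (s == "free").mean(), n_effective="size")
    out = out.reset_index()
    out["truth"] = truth
    out["rate_type"] = "FP" if truth == "invariant" else "TP"
    half = 1.96 * np.sqrt(nominal * (1 - nominal) / out["n_effective"])
    out["band_low"] = np.round(nominal - half, 10)
    out["band_high"] = np.round(nominal + half, 10)
    return out


def fp_acceptance_band(n_reps: int = 200, nominal: float = 0.05,
                       ndigits: int = 2) -> tuple[float, float]:
    """Binomial acceptability band for FP rates at the nominal alpha."""
    half = 1.96 * np.sqrt(nominal * (1.0 - nominal) / n_reps)
    return round(nominal - half, ndigits), round(nominal + half, ndigits)


def latent_effect_size(mean_diff: float, sd1: float, sd2: float) -> float:
    """Standardized latent mean difference with the pooled denominator
    sqrt((sd1^2 + sd2^2) / 2)."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    return abs(mean_diff) / np.sqrt((sd1**2 + sd2**2) / 2.0)


ANOVA_FACTORS = ("mean_diff", "lvar_ratio", "n_noninv_items",
                 "noninv_magnitude", "n_per_group")


def eta_squared(data: pd.DataFrame, response: str = "delta",
                factors: tuple[str, ...] = ANOVA_FACTORS,
                max_interaction_degree: int = 5) -> pd.DataFrame:
    """Full-factorial ANOVA eta-squared decomposition.

    Every factor is categorical; all interactions up to
    ``max_interaction_degree`` are included.  eta^2 = SS_term / SS_total
    (SS_total includes the residual).  Requires a fully crossed design.
    """
    df = data.dropna(subset=[response]).copy()
    cells = df.groupby(list(factors)).size()
    expected = int(np.prod([df[f].nunique() for f in factors]))
    if len(cells) != expected:
        raise ValueError(
            f"design is not fully crossed: {len(cells)} of {expected} cells present"
        )
    terms = " + ".join(f"C({f})" for f in factors)
    formula = f"{response} ~ ({terms}) ** {max_interaction_degree}"
    model = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    ss_total = table["sum_sq"].sum()
    out = table.loc[table.index != "Residual", ["sum_sq", "df"]].copy()
    out["eta_sq"] = out["sum_sq"] / ss_total
    out.index = [t.replace("C(", "").replace(")", "") for t in out.index]
    out.index.name = "term"
    return out


def anova_by_measure(decisions: pd.DataFrame, side: str,
                     max_interaction_degree: int = 5) -> pd.DataFrame:
    """eta-squared tables for every measure's fit-value difference on one
    comparison side ('loading' -> metric testing, 'intercept' -> scalar)."""
    comparison = "metric" if side == "loading" else "scalar"
    df = decisions[(decisions["noninv_location"] == side)
                   & (decisions["comparison"] == comparison)]
    if df.empty:
        raise ValueError(f"no decisions for side {side!r}")
    frames = []
    for measure, sub in df.groupby("measure"):
        tab = eta_squared(sub, max_interaction_degree=max_interaction_degree)
        tab = tab.reset_index()
        tab.insert(0, "measure", measure)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)
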