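"""Multigroup one-factor CFA by maximum likelihood.

Model levels
------------
configural
    All loadings, intercepts and error variances free in each group; the
    latent factor is standardized (mean 0, variance 1) in both groups.
metric
    Loadings constrained equal across groups; the focal group's latent
    variance is freed, latent means fixed at 0 in both groups.
scalar
    Loadings and intercepts constrained equal; the focal group's latent
    mean and variance are freed.
baseline
    Independence model: per-group means and variances free, all
    covariances zero.  Used by the incremental fit indices.

The discrepancy minimized is the multivariate-normal ML fitting function

    F_g = log|Sigma| - log|S_g| + tr(S_g Sigma^-1) - p
          + (xbar_g - mu)' Sigma^-1 (xbar_g - mu),

combined across groups as F = sum_g (n_g / N) F_g, with the chi-square
statistic T = N * F (an (N-1)-scaled variant is available).  Optimization
is quasi-Newton (L-BFGS-B) on a transformed vector in which variances are
log-scaled, with analytic gradients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .synthetic_data import TwoGroupDataset

LEVELS = ("configural", "metric", "scalar", "baseline")

_LOG_2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# model specification and parameter layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Slot:
    """One contiguous block of the free-parameter vector.

    ``group`` is 0/1 for group-specific blocks, None for blocks shared
    across groups.  ``log_scale`` marks variance blocks stored as logs.
    """

    name: str  # lam | nu | psi | phi | kappa
    group: int | None
    start: int
    size: int
    log_scale: bool = False

    @property
    def stop(self) -> int:
        return self.start + self.size


@dataclass(frozen=True)
class ModelSpec:
    """Invariance level plus item count; owns the free-parameter layout."""

    level: str
    n_items: int = 12

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}; expected one of {LEVELS}")

    @property
    def slots(self) -> tuple[Slot, ...]:
        p = self.n_items
        defs: list[tuple[str, int | None, int, bool]]
        if self.level == "configural":
            defs = [("lam", 0, p, False), ("lam", 1, p, False),
                    ("nu", 0, p, False), ("nu", 1, p, False),
                    ("psi", 0, p, True), ("psi", 1, p, True)]
        elif self.level == "metric":
            defs = [("lam", None, p, False),
                    ("nu", 0, p, False), ("nu", 1, p, False),
                    ("psi", 0, p, True), ("psi", 1, p, True),
                    ("phi", 1, 1, True)]
        elif self.level == "scalar":
            defs = [("lam", None, p, False), ("nu", None, p, False),
                    ("psi", 0, p, True), ("psi", 1, p, True),
                    ("phi", 1, 1, True), ("kappa", 1, 1, False)]
        else:  # baseline
            defs = [("nu", 0, p, False), ("nu", 1, p, False),
                    ("psi", 0, p, True), ("psi", 1, p, True)]
        out, pos = [], 0
        for name, group, size, log in defs:
            out.append(Slot(name, group, pos, size, log))
            pos += size
        return tuple(out)

    @property
    def n_free(self) -> int:
        return sum(s.size for s in self.slots)

    @property
    def param_names(self) -> list[str]:
        names = []
        for s in self.slots:
            tag = "" if s.group is None else f"g{s.group + 1},"
            if s.size == 1:
                names.append(f"{s.name}[{tag.rstrip(',')}]" if tag else s.name)
            else:
                names += [f"{s.name}[{tag}{i + 1}]" for i in range(s.size)]
        return names

    def parameter_table(self) -> list[dict]:
        """Every model parameter with its status (free/fixed/shared).

        Enumerates, per group, all loadings, intercepts, error variances,
        the latent mean and the latent variance, so the free count can be
        audited independently of the packed layout.
        """
        p = self.n_items
        rows = []
        for g in (0, 1):
            for name, size in (("lam", p), ("nu", p), ("psi", p),
                               ("kappa", 1), ("phi", 1)):
                for i in range(size):
                    rows.append({"group": g, "name": name, "index": i,
                                 "status": self._status(name, g)})
        return rows

    def _status(self, name: str, g: int) -> str:
        lv = self.level
        if name == "lam":
            if lv == "baseline":
                return "fixed"
            if lv == "configural":
                return "free"
            return "shared" if g == 1 else "free"
        if name == "nu":
            if lv == "scalar":
                return "shared" if g == 1 else "free"
            return "free"
        if name == "psi":
            return "free"
        if name == "kappa":
            return "free" if (lv == "scalar" and g == 1) else "fixed"
        if name == "phi":
            return "free" if (lv in ("metric", "scalar") and g == 1) else "fixed"
        raise KeyError(name)

    # -- packing ----------------------------------------------------------
    def unpack(self, x: np.ndarray) -> list[dict]:
        """Flat transformed vector -> per-group natural-scale parameters."""
        x = np.asarray(x, float)
        if x.shape != (self.n_free,):
            raise ValueError(f"expected {self.n_free} parameters, got {x.shape}")
        p = self.n_items
        base = {"lam": np.zeros(p) if self.level == "baseline" else None,
                "nu": None, "psi": None, "kappa": 0.0, "phi": 1.0}
        groups = [dict(base), dict(base)]
        for s in self.slots:
            val = np.exp(x[s.start:s.stop]) if s.log_scale else x[s.start:s.stop].copy()
            if s.size == 1:
                val = float(val[0])
            targets = (0, 1) if s.group is None else (s.group,)
            for g in targets:
                groups[g][s.name] = val
        for g, pars in enumerate(groups):
            missing = [k for k, v in pars.items() if v is None]
            if missing:
                raise ValueError(f"incomplete parameter vector: missing {missing} for group {g + 1}")
        return groups

    def pack(self, groups: list[dict]) -> np.ndarray:
        """Per-group natural-scale parameters -> flat transformed vector."""
        x = np.empty(self.n_free)
        for s in self.slots:
            g = 0 if s.group is None else s.group
            val = np.atleast_1d(np.asarray(groups[g][s.name], float))
            x[s.start:s.stop] = np.log(val) if s.log_scale else val
        return x


# ---------------------------------------------------------------------------
# sample and implied moments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleMoments:
    """Per-group mean vectors and ML (divisor-n) covariance matrices."""

    means: tuple[np.ndarray, np.ndarray]
    covs: tuple[np.ndarray, np.ndarray]
    sizes: tuple[int, int]

    @property
    def n_items(self) -> int:
        return self.means[0].shape[0]

    @property
    def n_total(self) -> int:
        return sum(self.sizes)

    def saturated_deviance(self) -> float:
        """-2 log-likelihood at the saturated model (mu = xbar, Sigma = S)."""
        p = self.n_items
        dev = 0.0
        for n, S in zip(self.sizes, self.covs):
            sign, logdet = np.linalg.slogdet(S)
            if sign <= 0:
                raise np.linalg.LinAlgError("singular sample covariance")
            dev += n * (p * _LOG_2PI + logdet + p)
        return dev


def sample_moments(dataset: TwoGroupDataset) -> SampleMoments:
    """Per-group means and biased (divisor n) covariance matrices."""
    n1, n2 = dataset.group_sizes
    if min(n1, n2) < 2:
        raise ValueError("need at least two observations per group")
    means, covs = [], []
    for y in (dataset.group1, dataset.group2):
        mu = y.mean(axis=0)
        yc = y - mu
        means.append(mu)
        covs.append(yc.T @ yc / y.shape[0])
    return SampleMoments(means=(means[0], means[1]), covs=(covs[0], covs[1]),
                         sizes=(n1, n2))


def implied_moments(params: dict) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean vector and covariance matrix for one group.

    mu = nu + lam * kappa;  Sigma = phi * lam lam' + diag(psi).
    """
    for key in ("lam", "nu", "psi", "kappa", "phi"):
        if key not in params or params[key] is None:
            raise ValueError(f"missing parameter {key!r}")
    lam = np.asarray(params["lam"], float)
    nu = np.asarray(params["nu"], float)
    psi = np.asarray(params["psi"], float)
    mu = nu + lam * params["kappa"]
    sigma = params["phi"] * np.outer(lam, lam) + np.diag(psi)
    return mu, sigma


def configural_reparam(lam, nu, kappa, phi):
    """Map generating parameters to their configural-model counterparts.

    Standardizing a N(kappa, phi) latent factor absorbs the latent
    distribution into the measurement parameters: lam_con = lam * sqrt(phi)
    and nu_con = nu + lam * kappa.
    """
    if phi <= 0:
        raise ValueError("phi must be positive")
    lam = np.asarray(lam, float)
    nu = np.asarray(nu, float)
    return lam * np.sqrt(phi), nu + lam * kappa


# ---------------------------------------------------------------------------
# discrepancy and gradient
# ---------------------------------------------------------------------------

def _group_f_and_grads(pars: dict, xbar, S, logdet_S):
    """F_g for one group plus gradients wrt natural-scale parameters."""
    mu, sigma = implied_moments(pars)
    cho = linalg.cho_factor(sigma, lower=True, check_finite=False)
    logdet = 2.0 * np.log(np.diag(cho[0])).sum()
    omega = linalg.cho_solve(cho, np.eye(len(mu)), check_finite=False)
    d = xbar - mu
    od = omega @ d
    os_ = omega @ S
    f = (logdet - logdet_S + np.trace(os_) - len(mu) + d @ od)
    # dF/dSigma and dF/dmu
    a = omega - os_ @ omega - np.outer(od, od)
    dmu = -2.0 * od
    lam = pars["lam"]
    grads = {
        "lam": 2.0 * pars["phi"] * (a @ lam) + pars["kappa"] * dmu,
        "nu": dmu,
        "psi": np.diag(a).copy(),
        "phi": float(lam @ a @ lam),
        "kappa": float(lam @ dmu),
    }
    return f, grads


def fml(x: np.ndarray, moments: SampleMoments, spec: ModelSpec,
        with_grad: bool = False):
    """Combined ML discrepancy F = sum_g (n_g/N) F_g (optionally with
    its gradient wrt the transformed free-parameter vector)."""
    groups = spec.unpack(x)
    n = moments.sizes
    w = np.asarray(n, float) / sum(n)
    logdets = []
    for S in moments.covs:
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            raise np.linalg.LinAlgError("singular sample covariance")
        logdets.append(logdet)

    total = 0.0
    per_group_grads = []
    for g in (0, 1):
        f, grads = _group_f_and_grads(groups[g], moments.means[g],
                                      moments.covs[g], logdets[g])
        total += w[g] * f
        per_group_grads.append(grads)
    if not with_grad:
        return total

    grad = np.zeros(spec.n_free)
    for s in spec.slots:
        targets = (0, 1) if s.group is None else (s.group,)
        acc = np.zeros(s.size)
        for g in targets:
            gval = np.atleast_1d(per_group_grads[g][s.name])
            if s.log_scale:  # chain rule through exp
                nat = np.atleast_1d(groups[g][s.name])
                gval = gval * nat
            acc += w[g] * gval
        grad[s.start:s.stop] = acc
    return total, grad


def deviance_from_f(f: float, moments: SampleMoments) -> float:
    """-2 log-likelihood: saturated deviance plus N * F."""
    return moments.saturated_deviance() + moments.n_total * f


def model_df(spec: ModelSpec) -> int:
    """Degrees of freedom: unique sample moments minus free parameters.

    With G = 2 groups and p items there are G * p(p+3)/2 moments
    (180 for p = 12).
    """
    p = spec.n_items
    p_star = 2 * p * (p + 3) // 2
    return p_star - spec.n_free


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class MLFitResult:
    spec: ModelSpec
    x: np.ndarray = field(repr=False)
    f_ml: float = np.nan
    t_stat: float = np.nan
    df: int = 0
    deviance: float = np.nan
    loglik: float = np.nan
    n_total: int = 0
    converged: bool = False
    n_retries: int = 0

    @property
    def params(self) -> list[dict]:
        return self.spec.unpack(self.x)

    @property
    def estimates(self) -> dict:
        return dict(zip(self.spec.param_names, self.x_natural))

    @property
    def x_natural(self) -> np.ndarray:
        out = self.x.copy()
        for s in self.spec.slots:
            if s.log_scale:
                out[s.start:s.stop] = np.exp(out[s.start:s.stop])
        return out

    def to_json(self) -> str:
        return json.dumps({
            "level": self.spec.level,
            "estimates": self.estimates,
            "F_ML": self.f_ml, "T": self.t_stat, "df": self.df,
            "deviance": self.deviance, "loglik": self.loglik,
            "converged": self.converged, "n_retries": self.n_retries,
        }, default=float)


def start_values(spec: ModelSpec, moments: SampleMoments) -> np.ndarray:
    """Deterministic starts: loadings 0.7, intercepts at the sample means,
    error variances at half the observed item variances, phi = 1, kappa = 0."""
    groups = []
    for g in (0, 1):
        groups.append({
            "lam": np.full(spec.n_items, 0.0 if spec.level == "baseline" else 0.7),
            "nu": moments.means[g].copy(),
            "psi": 0.5 * np.diag(moments.covs[g])
            if spec.level != "baseline" else np.diag(moments.covs[g]).copy(),
            "kappa": 0.0,
            "phi": 1.0,
        })
    return spec.pack(groups)


def _fit_baseline(spec: ModelSpec, moments: SampleMoments,
                  t_scale: str) -> MLFitResult:
    # closed form: means at xbar, variances at diag(S), covariances zero
    groups = [{"lam": np.zeros(spec.n_items), "nu": moments.means[g].copy(),
               "psi": np.diag(moments.covs[g]).copy(), "kappa": 0.0, "phi": 1.0}
              for g in (0, 1)]
    x = spec.pack(groups)
    f = fml(x, moments, spec)
    return _finalize(spec, x, f, moments, t_scale, True, 0)


def _finalize(spec, x, f, moments, t_scale, converged, retries) -> MLFitResult:
    n_total = moments.n_total
    scale = n_total if t_scale == "N" else n_total - 1
    dev = deviance_from_f(f, moments)
    return MLFitResult(
        spec=spec, x=np.asarray(x), f_ml=float(f), t_stat=float(scale * f),
        df=model_df(spec), deviance=float(dev), loglik=float(-0.5 * dev),
        n_total=n_total, converged=bool(converged), n_retries=retries,
    )


def fit_ml(spec: ModelSpec, moments: SampleMoments, *, t_scale: str = "N",
           max_retries: int = 5, gtol: float = 1e-6,
           rng: np.random.Generator | None = None) -> MLFitResult:
    """Minimize the ML discrepancy under the invariance constraints.

    Quasi-Newton with analytic gradients on the transformed vector
    (variances log-scaled, so Heywood cases cannot occur); up to
    ``max_retries`` restarts with multiplicatively jittered start values.
    Error variances collapsing below 1e-6 flag nonconvergence.
    """
    if t_scale not in ("N", "N-1"):
        raise ValueError("t_scale must be 'N' or 'N-1'")
    if moments.n_items != spec.n_items:
        raise ValueError("moments and spec disagree on the number of items")
    if spec.level == "baseline":
        return _fit_baseline(spec, moments, t_scale)

    x0 = start_values(spec, moments)
    rng = rng or np.random.default_rng(0)
    best = None
    for attempt in range(max_retries + 1):
        start = x0 if attempt == 0 else x0 * rng.uniform(0.8, 1.2, size=x0.shape)
        res = optimize.minimize(
            fml, start, args=(moments, spec, True), jac=True,
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": gtol},
        )
        groups = spec.unpack(res.x)
        heywood = any(np.min(np.atleast_1d(g["psi"])) < 1e-6 for g in groups)
        ok = (res.success or np.max(np.abs(res.jac)) < 1e-4) and not heywood
        if best is None or res.fun < best[1].fun:
            best = (ok, res, attempt)
        if ok:
            best = (ok, res, attempt)
            break
    ok, res, attempt = best
    return _finalize(spec, res.x, res.fun, moments, t_scale, ok, attempt)
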