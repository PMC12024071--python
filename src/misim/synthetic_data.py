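"""Population specification and data generation for two-group one-factor CFA.

The simulated measurement design: 12 continuous indicators loading on a
single factor, two groups of equal size.  Group 1 is the reference group
with a standard-normal latent distribution; group 2 (the focal group) may
differ in latent mean (0 or 0.8), latent variance (1, 2 or 4 times the
reference), and in the measurement parameters of a subset of items
(loadings or intercepts lowered by 0.15 or 0.25 for 1 or 4 items).

Error variances are tied to the latent variance as (1 - lambda^2) * phi_g,
so the population variance of every invariant item equals phi_g exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_ITEMS = 12
BASE_LOADING = 0.7

SAMPLE_SIZES = (100, 300, 600)
LVAR_RATIOS = (1.0, 2.0, 4.0)
MEAN_DIFFS = (0.0, 0.8)
NONINV_COUNTS = (1, 4)
NONINV_MAGNITUDES = (0.15, 0.25)
NONINV_LOCATIONS = ("loading", "intercept")


@dataclass(frozen=True)
class PopulationSpec:
    """Generating parameters for one simulation condition.

    Arrays are per group: index 0 is the reference group, index 1 the focal
    group.  ``loadings``/``intercepts``/``error_vars`` have one entry per
    item; ``latent_mean``/``latent_var`` are scalars per group.
    """

    n_per_group: int
    lvar_ratio: float
    mean_diff: float
    n_noninv_items: int
    noninv_magnitude: float
    noninv_location: str  # "loading" | "intercept" | "none"
    loadings: tuple[tuple[float, ...], tuple[float, ...]] = field(repr=False)
    intercepts: tuple[tuple[float, ...], tuple[float, ...]] = field(repr=False)
    error_vars: tuple[tuple[float, ...], tuple[float, ...]] = field(repr=False)
    latent_mean: tuple[float, float] = (0.0, 0.0)
    latent_var: tuple[float, float] = (1.0, 1.0)

    @property
    def label(self) -> str:
        """Compact condition identifier used in output tables."""
        return (
            f"n{self.n_per_group}_lvar{self.lvar_ratio:g}_md{self.mean_diff:g}"
            f"_{self.noninv_location}_ni{self.n_noninv_items}"
            f"_mag{self.noninv_magnitude:g}"
        )

    @property
    def is_invariant(self) -> bool:
        return self.noninv_location == "none"

    def group_params(self, g: int) -> dict:
        """Parameter dict (lam, nu, psi, kappa, phi) for group ``g`` in {0, 1}."""
        return {
            "lam": np.asarray(self.loadings[g]),
            "nu": np.asarray(self.intercepts[g]),
            "psi": np.asarray(self.error_vars[g]),
            "kappa": self.latent_mean[g],
            "phi": self.latent_var[g],
        }


@dataclass(frozen=True)
class TwoGroupDataset:
    """Observed indicator scores for both groups of one replication."""

    group1: np.ndarray  # (n, p)
    group2: np.ndarray  # (n, p)
    seed: int | None = None
    condition: str = ""

    def __post_init__(self):
        if self.group1.ndim != 2 or self.group2.ndim != 2:
            raise ValueError("group matrices must be 2-dimensional")
        if self.group1.shape[1] != self.group2.shape[1]:
            raise ValueError("groups must share the same item count")
        if np.isnan(self.group1).any() or np.isnan(self.group2).any():
            raise ValueError("missing values are not supported")

    @property
    def n_items(self) -> int:
        return self.group1.shape[1]

    @property
    def group_sizes(self) -> tuple[int, int]:
        return self.group1.shape[0], self.group2.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Wide layout: one row per subject, ``group`` column coded 1/2."""
        p = self.n_items
        cols = [f"item{i + 1:02d}" for i in range(p)]
        df = pd.DataFrame(np.vstack([self.group1, self.group2]), columns=cols)
        df.insert(0, "group", np.repeat([1, 2], self.group_sizes))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, condition: str = "") -> "TwoGroupDataset":
        if "group" not in df.columns:
            raise ValueError("expected a 'group' column coded 1/2")
        items = [c for c in df.columns if c != "group"]
        g1 = df.loc[df["group"] == 1, items].to_numpy(float)
        g2 = df.loc[df["group"] == 2, items].to_numpy(float)
        return cls(group1=g1, group2=g2, condition=condition)


def _validate(name: str, value, allowed) -> None:
    if value not in allowed:
        raise ValueError(f"invalid {name}={value!r}; allowed: {sorted(allowed)}")


def make_population(
    n_per_group: int,
    lvar_ratio: float,
    mean_diff: float,
    n_noninv_items: int = 0,
    noninv_magnitude: float = 0.0,
    noninv_location: str = "none",
) -> PopulationSpec:
    """Build the generating parameters for one condition.

    All loadings start at 0.7 and all intercepts at 0 in both groups.
    Noninvariance lowers the focal group's loading or intercept of the first
    ``n_noninv_items`` items by ``noninv_magnitude`` (items are exchangeable
    in this design, so the affected set is fixed to the leading items).
    Error variances are (1 - lambda^2) * phi_g elementwise, so every item's
    population variance equals phi_g and item variances track the latent
    variance one-for-one.
    """
    if n_per_group < 2:
        raise ValueError(f"invalid n_per_group={n_per_group}; need at least 2")
    _validate("lvar_ratio", float(lvar_ratio), set(map(float, LVAR_RATIOS)))
    _validate("mean_diff", float(mean_diff), set(map(float, MEAN_DIFFS)))
    if noninv_location == "none":
        if n_noninv_items != 0 or noninv_magnitude != 0.0:
            raise ValueError(
                "noninv_location='none' requires n_noninv_items=0 and magnitude=0"
            )
    else:
        _validate("noninv_location", noninv_location, set(NONINV_LOCATIONS))
        _validate("n_noninv_items", n_noninv_items, set(NONINV_COUNTS))
        _validate(
            "noninv_magnitude", float(noninv_magnitude), set(map(float, NONINV_MAGNITUDES))
        )

    lam1 = np.full(N_ITEMS, BASE_LOADING)
    nu1 = np.zeros(N_ITEMS)
    lam2, nu2 = lam1.copy(), nu1.copy()
    if noninv_location == "loading":
        lam2[:n_noninv_items] -= noninv_magnitude
    elif noninv_location == "intercept":
        nu2[:n_noninv_items] -= noninv_magnitude

    phi = (1.0, float(lvar_ratio))
    # each group's own loadings, so item variance is exactly phi_g even
    # for noninvariant-loading items
    psi1 = (1.0 - lam1**2) * phi[0]
    psi2 = (1.0 - lam2**2) * phi[1]

    return PopulationSpec(
        n_per_group=n_per_group,
        lvar_ratio=float(lvar_ratio),
        mean_diff=float(mean_diff),
        n_noninv_items=n_noninv_items,
        noninv_magnitude=float(noninv_magnitude),
        noninv_location=noninv_location,
        loadings=(tuple(lam1), tuple(lam2)),
        intercepts=(tuple(nu1), tuple(nu2)),
        error_vars=(tuple(psi1), tuple(psi2)),
        latent_mean=(0.0, float(mean_diff)),
        latent_var=phi,
    )


def condition_grid(include_invariant: bool = False) -> list[PopulationSpec]:
    """Fully crossed simulation grid.

    144 noninvariant conditions (3 sample sizes x 3 variance ratios x
    2 mean differences x 2 item counts x 2 magnitudes x 2 locations);
    with ``include_invariant`` the 18 invariant conditions are appended.
    """
    grid = [
        make_population(n, lv, md, ni, mag, loc)
        for n, lv, md, loc, ni, mag in itertools.product(
            SAMPLE_SIZES, LVAR_RATIOS, MEAN_DIFFS,
            NONINV_LOCATIONS, NONINV_COUNTS, NONINV_MAGNITUDES,
        )
    ]
    if include_invariant:
        grid += [
            make_population(n, lv, md)
            for n, lv, md in itertools.product(SAMPLE_SIZES, LVAR_RATIOS, MEAN_DIFFS)
        ]
    return grid


def generate_dataset(spec: PopulationSpec, seed) -> TwoGroupDataset:
    """Draw one replication: xi ~ N(kappa_g, phi_g), delta ~ N(0, Psi_g),
    y = nu_g + lambda_g * xi + delta.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`.
    """
    if any(v <= 0 for g in (0, 1) for v in spec.error_vars[g]):
        raise ValueError("error variances must be positive")
    if any(v <= 0 for v in spec.latent_var):
        raise ValueError("latent variances must be positive")
    rng = np.random.default_rng(seed)
    n = spec.n_per_group
    groups = []
    for g in (0, 1):
        pars = spec.group_params(g)
        xi = rng.normal(pars["kappa"], np.sqrt(pars["phi"]), size=n)
        delta = rng.normal(0.0, np.sqrt(pars["psi"]), size=(n, N_ITEMS))
        groups.append(pars["nu"] + np.outer(xi, pars["lam"]) + delta)
    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    return TwoGroupDataset(
        group1=groups[0], group2=groups[1], seed=seed_int, condition=spec.label
    )


def replication_seed(master_seed: int, condition_index: int, rep_index: int) -> np.random.SeedSequence:
    """Deterministic per-replication seed so any single replication can be
    regenerated in isolation."""
    return np.random.SeedSequence((int(master_seed), int(condition_index), int(rep_index)))
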