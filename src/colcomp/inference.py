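"""Bootstrap uncertainty and the trade-off correlation test.

Two resampling schemes mirror the structure of the data:

* **Seed-trap bootstrap** — traps (with their counts) are resampled with
  replacement and the seed-shadow model is refit, propagating uncertainty
  into the fecundity parameter, kernel parameters, colonization ability
  1/t and long-distance dispersal.
* **Quadrat bootstrap** — 20 x 20 m quadrats occupied by the species are
  resampled with replacement and the survival model refit on the pooled
  focals, preserving spatial correlation in survival; the crowding
  percentile stays fixed at its full-data value.

All intervals are 95% percentile intervals (2.5th and 97.5th percentiles of
the replicate distribution).

Cross-species relationships are tested with a paired bootstrap: for each of
``n_draw`` draws, one replicate value per species is sampled independently
from each quantity's bootstrap distribution, the cross-species correlation
is computed, and the percentile interval of the draw correlations is the
confidence interval.  A significant negative correlation between 1/t and
SOR under high crowding is evidence of a competition-colonization
trade-off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .colonization import gap_probability_batch, random_gap_placements
from .competition import (
    NotPredictedError,
    SurvivalFit,
    SurvivalFitError,
    fit_survival,
    survival_odds_ratio,
)
from .data import SeedDataset
from .kernels import KernelSpec, long_distance_dispersal
from .seed_shadow import (
    FitError,
    SeedShadowFit,
    _fit_from_workspace,
    _Workspace,
    basal_area,
)

__all__ = [
    "BootstrapDistribution",
    "CorrelationResult",
    "assign_quadrats",
    "bootstrap_seed_traps",
    "bootstrap_quadrats",
    "paired_bootstrap_correlation",
]

log = logging.getLogger(__name__)

MAX_FAILURE_FRACTION = 0.2


@dataclass
class BootstrapDistribution:
    """Replicate estimates of one scalar quantity."""

    label: str
    values: np.ndarray
    n_failed: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    def ci(self, level: float = 95.0) -> tuple[float, float]:
        half = (100.0 - level) / 2.0
        lo, hi = np.percentile(self.values, [half, 100.0 - half])
        return float(lo), float(hi)


@dataclass(frozen=True)
class CorrelationResult:
    """Cross-species correlation with paired-bootstrap confidence interval."""

    label: str
    r: float
    ci_low: float
    ci_high: float
    n_species: int
    method: str = "pearson"
    draws: np.ndarray = field(default=None, repr=False, compare=False)

    @property
    def significant(self) -> bool:
        return not (self.ci_low <= 0.0 <= self.ci_high)

    def to_json(self) -> dict:
        return {
            "label": self.label,
            "r": self.r,
            "ci": [self.ci_low, self.ci_high],
            "n_species": self.n_species,
            "method": self.method,
            "significant": self.significant,
        }


def _check_failures(n_failed: int, n_boot: int, what: str) -> None:
    if n_failed > MAX_FAILURE_FRACTION * n_boot:
        raise RuntimeError(
            f"{n_failed}/{n_boot} {what} bootstrap replicates failed; "
            "inspect the model or the data before trusting any interval"
        )
    if n_failed:
        log.warning("%d/%d %s bootstrap replicates failed and were dropped",
                    n_failed, n_boot, what)


# ---------------------------------------------------------------------------
# seed-trap bootstrap
# ---------------------------------------------------------------------------

def bootstrap_seed_traps(
    dataset: SeedDataset,
    species: str,
    baseline: SeedShadowFit,
    n_boot: int = 1000,
    seed: int = 0,
    dbh_values: tuple[float, ...] = (5.0, 10.0, 20.0),
    gap_size: tuple[float, float] = (10.0, 10.0),
    n_gap_placements: int = 1000,
    placement_seed: int = 0,
    ldd_threshold: float = 50.0,
) -> dict[str, BootstrapDistribution]:
    """Trap bootstrap of the seed-shadow fit and the quantities derived
    from it (beta, kernel parameters, 1/t at each DBH, LDD).

    Every replicate resamples the same number of traps as observed, with
    replacement, refits the baseline's kernel family (warm-started at the
    baseline estimate plus the deterministic grid), and recomputes the
    derived quantities with the gap placements held fixed.
    """
    rng = np.random.default_rng(seed)
    ws = _Workspace(dataset, species)
    n_traps = len(ws.counts)
    family = baseline.kernel.family
    mother = (dataset.plot[0] / 2.0, dataset.plot[1] / 2.0)
    gaps = random_gap_placements(dataset.plot, n_gap_placements, gap_size, placement_seed)
    warm = [np.log(np.asarray(baseline.kernel.params))]

    keys = (
        ["beta"]
        + [f"b{i+1}" for i in range(baseline.kernel.n_params)]
        + ["p_gap"]
        + [f"inv_t_{d:g}" for d in dbh_values]
        + ["ldd"]
    )
    reps: dict[str, list[float]] = {k: [] for k in keys}
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n_traps, size=n_traps)
        try:
            fit = _fit_from_workspace(ws.subset(idx), species, family, starts=warm)
        except FitError:
            n_failed += 1
            continue
        p_gap = float(gap_probability_batch(fit.kernel, mother, gaps).mean())
        reps["beta"].append(fit.beta)
        for i, p in enumerate(fit.kernel.params):
            reps[f"b{i+1}"].append(p)
        reps["p_gap"].append(p_gap)
        for d in dbh_values:
            reps[f"inv_t_{d:g}"].append(p_gap * fit.beta * basal_area(d))
        reps["ldd"].append(long_distance_dispersal(fit.kernel, ldd_threshold))

    _check_failures(n_failed, n_boot, "seed-trap")
    return {k: BootstrapDistribution(k, np.array(v), n_failed) for k, v in reps.items()}


# ---------------------------------------------------------------------------
# quadrat bootstrap
# ---------------------------------------------------------------------------

def assign_quadrats(trees: pd.DataFrame, plot: tuple[float, float], size: float = 20.0) -> pd.Series:
    """Integer quadrat id of each stem on a ``size`` x ``size`` m grid."""
    ncol = int(np.ceil(plot[0] / size))
    qx = np.minimum((trees["x"].to_numpy(float) / size).astype(int), ncol - 1)
    qy = (trees["y"].to_numpy(float) / size).astype(int)
    return pd.Series(qy * ncol + qx, index=trees.index, name="quadrat")


def bootstrap_quadrats(
    focals: pd.DataFrame,
    nc_star: float,
    species: str = "",
    dbh_values: tuple[float, ...] = (5.0, 10.0, 20.0),
    dbh_m: float | None = None,
    quadrat: pd.Series | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, BootstrapDistribution]:
    """Quadrat bootstrap of the survival model and SOR at each DBH.

    ``focals`` holds one species' usable focal trees (columns ``dbh``,
    ``nc``, ``survived`` and either a ``quadrat`` column or a separate
    ``quadrat`` series).  Each replicate resamples, with replacement, the
    same number of occupied 20 x 20 m quadrats as the species occupies and
    pools their trees (a quadrat drawn twice contributes its trees twice).
    The crowding percentile ``nc_star`` is held at its full-data value.
    """
    if quadrat is None:
        if "quadrat" not in focals.columns:
            raise ValueError("focals need a 'quadrat' column or an explicit quadrat series")
        quadrat = focals["quadrat"]
    quadrat = np.asarray(quadrat)
    occupied = np.unique(quadrat)
    if occupied.size < 2:
        raise ValueError(
            f"species {species or ''} occupies {occupied.size} quadrat(s); "
            "at least 2 are needed to resample"
        )
    groups = {q: np.flatnonzero(quadrat == q) for q in occupied}
    rng = np.random.default_rng(seed)

    sizes = [d for d in dbh_values if dbh_m is None or d <= dbh_m]
    keys = ["intercept", "coef_dbh", "coef_nc"] + [f"sor_{d:g}" for d in sizes]
    reps: dict[str, list[float]] = {k: [] for k in keys}
    n_failed = 0
    for _ in range(n_boot):
        chosen = rng.choice(occupied, size=occupied.size, replace=True)
        rows = np.concatenate([groups[q] for q in chosen])
        try:
            fit = fit_survival(focals.iloc[rows], species=species)
        except SurvivalFitError:
            n_failed += 1
            continue
        reps["intercept"].append(fit.intercept)
        reps["coef_dbh"].append(fit.coef_dbh)
        reps["coef_nc"].append(fit.coef_nc)
        for d in sizes:
            reps[f"sor_{d:g}"].append(survival_odds_ratio(fit, d, nc_star, dbh_m))

    _check_failures(n_failed, n_boot, "quadrat")
    return {k: BootstrapDistribution(k, np.array(v), n_failed) for k, v in reps.items()}


# ---------------------------------------------------------------------------
# paired bootstrap correlation
# ---------------------------------------------------------------------------

def _corr(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def paired_bootstrap_correlation(
    boot_a: dict[str, BootstrapDistribution],
    boot_b: dict[str, BootstrapDistribution],
    label: str = "",
    n_draw: int = 1000,
    seed: int = 0,
    method: str = "pearson",
) -> CorrelationResult:
    """Cross-species correlation between two bootstrapped quantities.

    ``boot_a`` and ``boot_b`` map species code to that species' bootstrap
    distribution of quantity A and B.  Each draw samples one replicate per
    species independently from each distribution and correlates across
    species; the CI is the 2.5/97.5 percentile interval of the ``n_draw``
    correlations.  The point estimate ``r`` correlates the per-species
    replicate means.
    """
    species = sorted(set(boot_a) & set(boot_b))
    if len(species) < 3:
        raise ValueError(f"need at least 3 shared species, got {len(species)}")
    rng = np.random.default_rng(seed)
    means_a = np.array([boot_a[s].mean for s in species])
    means_b = np.array([boot_b[s].mean for s in species])
    r = _corr(means_a, means_b, method)

    draws_a = np.column_stack(
        [rng.choice(boot_a[s].values, size=n_draw, replace=True) for s in species]
    )
    draws_b = np.column_stack(
        [rng.choice(boot_b[s].values, size=n_draw, replace=True) for s in species]
    )
    if method == "spearman":
        draws_a = stats.rankdata(draws_a, axis=1)
        draws_b = stats.rankdata(draws_b, axis=1)
    za = draws_a - draws_a.mean(axis=1, keepdims=True)
    zb = draws_b - draws_b.mean(axis=1, keepdims=True)
    denom = np.sqrt((za**2).sum(axis=1) * (zb**2).sum(axis=1))
    with np.errstate(invalid="ignore"):
        rs = np.where(denom > 0, (za * zb).sum(axis=1) / denom, 0.0)
    lo, hi = np.percentile(rs, [2.5, 97.5])
    return CorrelationResult(
        label=label, r=r, ci_low=float(lo), ci_high=float(hi),
        n_species=len(species), method=method, draws=rs,
    )
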