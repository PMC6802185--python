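"""Inverse modeling of seed shadows from mapped trees and seed traps.

The seed shadow of a mother tree is ``F(dbh) * P(r)``: size-specific annual
fecundity times the dispersal kernel.  Fecundity is proportional to basal
area through a single size-independent parameter ``beta`` (seeds per cm^2 of
basal area per year), so the expected count in trap ``k`` over a window of
``T`` years is

    lambda_k = T * area_k * sum_i beta * BA(dbh_i) * P(d_ik)

summing over conspecific stems at or above the reproductive threshold.
Observed trap counts are modeled as independent Poisson draws with these
means, and ``beta`` and the kernel parameters are estimated jointly by
maximum likelihood; candidate kernel families are compared by AIC.

Because ``beta`` enters the mean linearly, it is profiled out analytically
(``beta_hat = N_total / sum_k c_k`` where ``lambda_k = beta * c_k``), and the
numerical search runs only over the one or two kernel parameters, on the log
scale to enforce positivity, from several deterministic starting points.
The profiled optimum coincides with the joint maximum-likelihood estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special
from scipy.spatial.distance import cdist

from .data import SeedDataset
from .kernels import FAMILIES, KernelSpec, kernel_density

__all__ = [
    "SeedShadowFit",
    "basal_area",
    "fecundity",
    "expected_trap_count",
    "expected_counts",
    "negative_log_likelihood",
    "fit_seed_shadow",
    "fit_all_families",
    "select_best_kernel",
]

_NLL_SENTINEL = 1e12


class FitError(RuntimeError):
    """Raised when a seed-shadow fit is impossible or fails to converge."""


def basal_area(dbh):
    """Basal area in cm^2 of a stem of diameter ``dbh`` (cm)."""
    dbh = np.asarray(dbh, dtype=float)
    if np.any(dbh <= 0):
        raise ValueError("dbh must be positive")
    out = np.pi * (dbh / 2.0) ** 2
    return float(out) if out.ndim == 0 else out


def fecundity(beta: float, dbh):
    """Annual seed production ``beta * BA(dbh)`` of a reproductive stem.

    ``beta`` is the size-independent allocation to reproduction per unit
    basal area (seeds cm^-2 yr^-1).
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    return beta * basal_area(dbh)


@dataclass(frozen=True)
class SeedShadowFit:
    """Jointly estimated fecundity and kernel parameters for one species."""

    species: str
    kernel: KernelSpec
    beta: float
    log_lik: float
    n_params: int
    converged: bool = True
    n_traps: int = 0
    total_seeds: int = 0

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.log_lik

    def to_json(self) -> dict:
        return {
            "species": self.species,
            "family": self.kernel.family,
            "params": list(self.kernel.params),
            "beta": self.beta,
            "logLik": self.log_lik,
            "n_params": self.n_params,
            "aic": self.aic,
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# expected counts and likelihood
# ---------------------------------------------------------------------------

def expected_counts(trees, traps, beta, kernel, years, dbh_r) -> np.ndarray:
    """Poisson means for every trap, given mapped conspecific stems.

    Only stems with ``dbh >= dbh_r`` contribute.  ``trees`` and ``traps``
    are DataFrames with ``x, y`` (m) columns; trees also need ``dbh`` (cm)
    and traps ``area`` (m^2).
    """
    if years <= 0:
        raise ValueError("years must be positive")
    repro = trees[trees["dbh"].to_numpy(float) >= dbh_r]
    areas = traps["area"].to_numpy(float)
    if len(repro) == 0:
        return np.zeros(len(traps))
    d = cdist(traps[["x", "y"]].to_numpy(float), repro[["x", "y"]].to_numpy(float))
    fec = fecundity(beta, repro["dbh"].to_numpy(float))
    dens = kernel_density(kernel, d.ravel()).reshape(d.shape)
    return years * areas * (dens @ fec)


def expected_trap_count(trees, trap, beta, kernel, years, dbh_r) -> float:
    """Expected seed count at a single trap (a one-row convenience wrapper)."""
    import pandas as pd

    traps = pd.DataFrame([{"x": trap["x"], "y": trap["y"], "area": trap["area"]}])
    return float(expected_counts(trees, traps, beta, kernel, years, dbh_r)[0])


def _poisson_nll(lam: np.ndarray, n: np.ndarray) -> float:
    """Sum over traps of ``lam - n ln lam + ln n!``; +inf-like sentinel when
    a zero mean faces a positive count."""
    lam = np.asarray(lam, float)
    n = np.asarray(n, float)
    bad = (lam <= 0) & (n > 0)
    if np.any(bad):
        return _NLL_SENTINEL
    terms = lam + special.gammaln(n + 1.0)
    pos = lam > 0
    terms[pos] -= n[pos] * np.log(lam[pos])
    return float(terms.sum())


def negative_log_likelihood(theta, dataset: SeedDataset, species: str, family: str) -> float:
    """Poisson negative log-likelihood at ``theta = (log beta, log kernel params)``."""
    theta = np.asarray(theta, float)
    if not np.all(np.isfinite(theta)):
        return _NLL_SENTINEL
    beta = math.exp(theta[0])
    kernel = KernelSpec(family, tuple(np.exp(theta[1:])))
    dbh_r = float(dataset.species_row(species)["dbh_r"])
    trees = dataset.trees[dataset.trees["species"] == species]
    lam = expected_counts(trees, dataset.traps, beta, kernel, dataset.years, dbh_r)
    return _poisson_nll(lam, dataset.trap_counts(species))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

class _Workspace:
    """Precomputed geometry for fast repeated likelihood evaluations."""

    def __init__(self, dataset: SeedDataset, species: str):
        dbh_r = float(dataset.species_row(species)["dbh_r"])
        repro = dataset.reproductive_trees(species)
        self.n_repro = len(repro)
        self.counts = dataset.trap_counts(species).astype(float)
        self.scale = dataset.years * dataset.traps["area"].to_numpy(float)
        self.log_fact = float(special.gammaln(self.counts + 1.0).sum())
        if self.n_repro:
            self.dist = cdist(
                dataset.traps[["x", "y"]].to_numpy(float),
                repro[["x", "y"]].to_numpy(float),
            )
            self.ba = basal_area(repro["dbh"].to_numpy(float))
        else:
            self.dist = np.zeros((len(dataset.traps), 0))
            self.ba = np.zeros(0)

    def subset(self, trap_idx: np.ndarray) -> "_Workspace":
        """A view resampled to the given trap rows (bootstrap support)."""
        ws = object.__new__(_Workspace)
        ws.n_repro = self.n_repro
        ws.counts = self.counts[trap_idx]
        ws.scale = self.scale[trap_idx]
        ws.log_fact = float(special.gammaln(ws.counts + 1.0).sum())
        ws.dist = self.dist[trap_idx]
        ws.ba = self.ba
        return ws

    def unit_means(self, kernel: KernelSpec) -> np.ndarray:
        """Per-trap mean at beta = 1: ``c_k = T a_k sum_i BA_i P(d_ik)``."""
        dens = kernel_density(kernel, self.dist.ravel()).reshape(self.dist.shape)
        return self.scale * (dens @ self.ba)

    def profiled_nll(self, log_params: np.ndarray, family: str):
        """NLL minimized over beta analytically; returns (nll, beta_hat)."""
        if not np.all(np.isfinite(log_params)) or np.any(np.abs(log_params) > 50):
            return _NLL_SENTINEL, np.nan
        try:
            kernel = KernelSpec(family, tuple(np.exp(log_params)))
        except ValueError:
            return _NLL_SENTINEL, np.nan
        c = self.unit_means(kernel)
        n_total = self.counts.sum()
        c_total = c.sum()
        if not np.isfinite(c_total) or c_total <= 0 or n_total <= 0:
            return _NLL_SENTINEL, np.nan
        beta = n_total / c_total
        return _poisson_nll(beta * c, self.counts), beta


def _start_grid(ws: _Workspace, family: str) -> list[np.ndarray]:
    """Deterministic multi-start points: kernel scales spanning the observed
    trap-to-tree distance quantiles, crossed with a few shapes."""
    if ws.dist.size:
        q = np.quantile(ws.dist, [0.02, 0.15])
        scales = np.unique(np.round(np.clip(q, 2.0, None), 1))
    else:
        scales = np.array([10.0])
    scales = np.union1d(scales, [5.0, 15.0, 40.0])
    starts: list[np.ndarray] = []
    if family == "negative_exponential":
        starts = [np.log([s]) for s in scales]
    elif family == "two_dim_t":
        starts = [np.log([s * s, p]) for s in scales for p in (0.8, 2.0)]
    elif family == "lognormal":
        starts = [np.log([s, b]) for s in scales for b in (0.6, 1.2)]
    else:  # weibull
        starts = [np.log([s, c]) for s in scales for c in (0.8, 1.6)]
    return starts


def _fit_from_workspace(
    ws: _Workspace,
    species: str,
    family: str,
    starts: list[np.ndarray] | None = None,
    tol: float = 1e-8,
) -> SeedShadowFit:
    if ws.n_repro == 0:
        raise FitError(f"species {species!r} has no reproductive trees")
    if ws.counts.sum() <= 0:
        raise FitError(f"species {species!r} has no trap with a positive count")
    if starts is None:
        starts = _start_grid(ws, family)

    best = None
    for x0 in starts:
        res = optimize.minimize(
            lambda x: ws.profiled_nll(x, family)[0],
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": tol, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    nll, beta = ws.profiled_nll(best.x, family)
    converged = bool(best.success and nll < _NLL_SENTINEL and np.isfinite(beta))
    if not converged:
        raise FitError(
            f"seed-shadow fit failed for {species!r}/{family}: "
            f"nll={nll:.3g}, success={best.success}"
        )
    kernel = KernelSpec(family, tuple(np.exp(best.x)))
    return SeedShadowFit(
        species=species,
        kernel=kernel,
        beta=float(beta),
        log_lik=-float(nll),
        n_params=1 + kernel.n_params,
        converged=converged,
        n_traps=len(ws.counts),
        total_seeds=int(ws.counts.sum()),
    )


def fit_seed_shadow(dataset: SeedDataset, species: str, family: str) -> SeedShadowFit:
    """Maximum-likelihood seed-shadow fit for one species and kernel family."""
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    ws = _Workspace(dataset, species)
    return _fit_from_workspace(ws, species, family)


def fit_all_families(dataset: SeedDataset, species: str, families=FAMILIES) -> dict[str, SeedShadowFit]:
    """Fit every requested kernel family; failed families are omitted."""
    ws = _Workspace(dataset, species)
    fits: dict[str, SeedShadowFit] = {}
    for fam in families:
        try:
            fits[fam] = _fit_from_workspace(ws, species, fam)
        except FitError:
            continue
    if not fits:
        raise FitError(f"all kernel-family fits failed for species {species!r}")
    return fits


def select_best_kernel(fits: dict[str, SeedShadowFit] | list[SeedShadowFit]) -> SeedShadowFit:
    """The fit with the lowest AIC.

    Exact AIC ties go to the family with fewer parameters, then to the fixed
    family order ``FAMILIES``.
    """
    if isinstance(fits, dict):
        fits = list(fits.values())
    fits = [f for f in fits if f.converged]
    if not fits:
        raise FitError("no converged fits to select among")
    return min(fits, key=lambda f: (f.aic, f.n_params, FAMILIES.index(f.kernel.family)))
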