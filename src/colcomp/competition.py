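"""Neighborhood crowding and competitive ability.

Competitive ability is survival under heavy crowding.  For focal tree ``i``
the neighborhood crowding index is

    NC_i = ln( sum_j pi (D_j / 2)^2 exp(-0.2 d_ij) )

over neighbors ``j`` of any species with strictly larger DBH within 15 m:
distance-decayed basal area of the stems that can shade the focal.  Survival
over one census interval is modeled per species by logistic regression on
initial DBH and NC.  Competitive ability is then the survival odds ratio
``SOR = s / (1 - s)`` predicted at the 97.5th percentile of NC pooled over
every individual in the plot — survival odds in the most crowded conditions
a tree encounters.

Focals with no larger neighbor inside the radius have an empty sum (ln 0),
so their NC is undefined; they are excluded from fits and from the
percentile pool.  Fits use only focals more than 15 m from every plot edge,
whose neighborhoods are fully observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial import cKDTree
from scipy.special import expit

__all__ = [
    "SurvivalFit",
    "NotPredictedError",
    "neighborhood_crowding",
    "crowding_table",
    "fit_survival",
    "crowding_percentile",
    "survival_odds_ratio",
]

DEFAULT_RADIUS = 15.0
DEFAULT_DECAY = 0.2
DEFAULT_EDGE_BUFFER = 15.0


class NotPredictedError(ValueError):
    """Survival is not predicted beyond a species' maximum observed DBH."""


class SurvivalFitError(RuntimeError):
    """Raised when a survival model cannot be fit at all."""


@dataclass(frozen=True)
class SurvivalFit:
    """Logistic survival coefficients (logit scale, one census interval)."""

    species: str
    intercept: float
    coef_dbh: float   # per cm of initial DBH
    coef_nc: float    # per unit of NC
    n_obs: int
    log_lik: float = np.nan
    converged: bool = True
    penalized: bool = False

    def linear_predictor(self, dbh, nc):
        return self.intercept + self.coef_dbh * np.asarray(dbh, float) + self.coef_nc * np.asarray(nc, float)

    def survival_probability(self, dbh, nc):
        return expit(self.linear_predictor(dbh, nc))

    def to_json(self) -> dict:
        return {
            "species": self.species,
            "intercept": self.intercept,
            "coef_dbh": self.coef_dbh,
            "coef_nc": self.coef_nc,
            "n_obs": self.n_obs,
            "logLik": None if np.isnan(self.log_lik) else self.log_lik,
            "converged": self.converged,
            "penalized": self.penalized,
        }


def crowding_table(
    trees: pd.DataFrame,
    plot: tuple[float, float],
    radius: float = DEFAULT_RADIUS,
    decay: float = DEFAULT_DECAY,
    edge_buffer: float = DEFAULT_EDGE_BUFFER,
) -> pd.DataFrame:
    """NC, neighbor count and edge flag for every stem in the census.

    Uses a k-d tree over all stems; neighbors are conspecific or not, with
    strictly larger DBH (strict inequality breaks ties) and 0 < d <= radius.
    Returns a DataFrame aligned to ``trees`` with columns ``nc`` (NaN when
    undefined), ``n_neighbors`` and ``edge_ok``.
    """
    xy = trees[["x", "y"]].to_numpy(float)
    dbh = trees["dbh"].to_numpy(float)
    n = len(trees)
    sums = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    if n > 1:
        tree = cKDTree(xy)
        pairs = tree.query_pairs(r=radius, output_type="ndarray")
        if len(pairs):
            i, j = pairs[:, 0], pairs[:, 1]
            d = np.hypot(xy[i, 0] - xy[j, 0], xy[i, 1] - xy[j, 1])
            w = np.exp(-decay * d)
            ba = np.pi * (dbh / 2.0) ** 2
            # j shades i where D_j > D_i, and vice versa; exact ties shade no one
            m = dbh[j] > dbh[i]
            np.add.at(sums, i[m], ba[j[m]] * w[m])
            np.add.at(counts, i[m], 1)
            m = dbh[i] > dbh[j]
            np.add.at(sums, j[m], ba[i[m]] * w[m])
            np.add.at(counts, j[m], 1)
    with np.errstate(divide="ignore"):
        nc = np.where(sums > 0, np.log(np.where(sums > 0, sums, 1.0)), np.nan)
    w_, h_ = plot
    edge_ok = (
        (xy[:, 0] > edge_buffer)
        & (xy[:, 0] < w_ - edge_buffer)
        & (xy[:, 1] > edge_buffer)
        & (xy[:, 1] < h_ - edge_buffer)
    )
    return pd.DataFrame(
        {"nc": nc, "n_neighbors": counts, "edge_ok": edge_ok}, index=trees.index
    )


def neighborhood_crowding(
    focal_id,
    trees: pd.DataFrame,
    radius: float = DEFAULT_RADIUS,
    decay: float = DEFAULT_DECAY,
) -> tuple[float, int]:
    """NC of a single focal stem (brute-force): ``(nc, n_neighbors)``,
    with ``nc = nan`` when no larger neighbor lies within the radius."""
    rows = trees[trees["id"] == focal_id]
    if len(rows) != 1:
        raise KeyError(f"focal tree {focal_id!r} not found (or duplicated)")
    f = rows.iloc[0]
    dx = trees["x"].to_numpy(float) - float(f["x"])
    dy = trees["y"].to_numpy(float) - float(f["y"])
    d = np.hypot(dx, dy)
    dbh = trees["dbh"].to_numpy(float)
    mask = (d > 0) & (d <= radius) & (dbh > float(f["dbh"]))
    if not mask.any():
        return np.nan, 0
    ba = np.pi * (dbh[mask] / 2.0) ** 2
    return float(np.log(np.sum(ba * np.exp(-decay * d[mask])))), int(mask.sum())


def fit_survival(
    df: pd.DataFrame,
    species: str = "",
    min_obs: int = 10,
    ridge_alpha: float = 1.0,
) -> SurvivalFit:
    """Logistic survival model ``logit(s) = a + b_dbh * DBH + b_nc * NC``.

    ``df`` must carry ``dbh``, ``nc`` and boolean ``survived``; rows with
    undefined NC or outside the edge buffer should already be excluded
    (``edge_ok`` is honored if present).  Complete separation, a one-class
    outcome, or non-convergence falls back to an L2-penalized fit, flagged
    via ``penalized``/``converged``.
    """
    if "edge_ok" in df.columns:
        df = df[df["edge_ok"]]
    df = df.dropna(subset=["nc"])
    n = len(df)
    if n < min_obs:
        raise SurvivalFitError(
            f"too few usable focal trees for {species or 'species'}: {n} < {min_obs}"
        )
    y = df["survived"].to_numpy(float)
    X = sm.add_constant(df[["dbh", "nc"]].to_numpy(float), has_constant="add")

    both_classes = 0 < y.sum() < n
    if both_classes:
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("error")
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
            params = np.asarray(res.params, float)
            if res.converged and np.all(np.abs(params) < 1e3):
                return SurvivalFit(
                    species, float(params[0]), float(params[1]), float(params[2]),
                    n_obs=n, log_lik=float(res.llf), converged=True,
                )
        except Exception:
            pass

    # Penalized fallback: ridge on the coefficients (not the intercept).
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(C=1.0 / ridge_alpha, solver="lbfgs", max_iter=1000)
    yb = y.astype(int)
    if yb.min() == yb.max():
        # Degenerate outcome: pin probabilities near the observed constant.
        p = np.clip(yb.mean(), 1e-4, 1 - 1e-4)
        return SurvivalFit(
            species, float(np.log(p / (1 - p))), 0.0, 0.0,
            n_obs=n, converged=False, penalized=True,
        )
    clf.fit(df[["dbh", "nc"]].to_numpy(float), yb)
    return SurvivalFit(
        species,
        float(clf.intercept_[0]),
        float(clf.coef_[0][0]),
        float(clf.coef_[0][1]),
        n_obs=n,
        converged=False,
        penalized=True,
    )


def crowding_percentile(nc_values, q: float = 97.5) -> float:
    """The ``q``-th percentile (linear interpolation) of the defined NC
    values pooled over every individual in the plot."""
    nc = np.asarray(nc_values, float)
    nc = nc[np.isfinite(nc)]
    if nc.size == 0:
        raise ValueError("no defined NC values")
    return float(np.percentile(nc, q))


def survival_odds_ratio(fit: SurvivalFit, dbh: float, nc: float, dbh_m: float | None = None) -> float:
    """Survival odds ``s / (1 - s)`` at the given size and crowding.

    Refuses sizes beyond the species' maximum observed DBH: survival is not
    extrapolated past the data.
    """
    if dbh_m is not None and dbh > dbh_m:
        raise NotPredictedError(
            f"dbh {dbh} cm exceeds the maximum observed size {dbh_m} cm for "
            f"{fit.species or 'this species'}"
        )
    # odds = exp(linear predictor) exactly; avoids s -> 1 overflow in s/(1-s)
    return float(np.exp(fit.linear_predictor(dbh, nc)))
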