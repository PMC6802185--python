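"""Tabular containers and CSV I/O for mapped-plot seed rain analyses.

The pipeline consumes four tables:

* a stem census: one row per mapped stem with coordinates (m), DBH (cm) and
  a survival outcome between two censuses;
* seed-trap locations with trap area (m^2);
* per-(trap, species) seed counts pooled over the observation window;
* species metadata: the reproductive DBH threshold ``dbh_r`` and the maximum
  observed DBH ``dbh_m`` (cm), plus an optional growth form label.

All tables are plain pandas DataFrames, bundled with the observation-window
length and plot geometry in a :class:`SeedDataset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SeedDataset",
    "read_census",
    "read_traps",
    "read_seed_counts",
    "read_species",
]

TREE_COLUMNS = ("id", "species", "x", "y", "dbh", "survived")
TRAP_COLUMNS = ("id", "x", "y", "area")
COUNT_COLUMNS = ("trap_id", "species", "count")
SPECIES_COLUMNS = ("code", "dbh_r", "dbh_m")


class DataValidationError(ValueError):
    """Raised when an input table violates the pipeline's contracts."""


def _require_columns(df: pd.DataFrame, cols, name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataValidationError(f"{name} table is missing columns {missing}")


@dataclass
class SeedDataset:
    """Mapped trees, seed traps, pooled seed counts and species metadata.

    Parameters
    ----------
    trees
        Columns ``id, species, x, y, dbh`` (cm) and optionally ``survived``
        (boolean outcome between the two censuses).
    traps
        Columns ``id, x, y, area`` (m^2; point traps of 0.5 m^2 by default).
    counts
        Long-format columns ``trap_id, species, count`` with counts pooled
        over the whole observation window; absent pairs mean zero.
    species
        Columns ``code, dbh_r, dbh_m`` and optionally ``growth_form``.
    years
        Length of the seed-trapping window in years.
    plot
        ``(width, height)`` of the rectangular plot in meters.
    """

    trees: pd.DataFrame
    traps: pd.DataFrame
    counts: pd.DataFrame
    species: pd.DataFrame
    years: float = 10.0
    plot: tuple[float, float] = (500.0, 400.0)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _require_columns(self.trees, [c for c in TREE_COLUMNS if c != "survived"], "trees")
        _require_columns(self.traps, TRAP_COLUMNS, "traps")
        _require_columns(self.counts, COUNT_COLUMNS, "counts")
        _require_columns(self.species, SPECIES_COLUMNS, "species")
        if self.years <= 0:
            raise DataValidationError("observation window must be positive")
        w, h = self.plot
        if w <= 0 or h <= 0:
            raise DataValidationError("plot dimensions must be positive")
        if len(self.trees) and float(self.trees["dbh"].min()) < 1.0:
            raise DataValidationError("census DBH below the 1 cm mapping threshold")
        for name, df in (("trees", self.trees), ("traps", self.traps)):
            if len(df) == 0:
                continue
            x, y = df["x"].to_numpy(float), df["y"].to_numpy(float)
            if x.min() < 0 or x.max() > w or y.min() < 0 or y.max() > h:
                raise DataValidationError(f"{name} coordinates fall outside the plot")
        if len(self.traps) and float(self.traps["area"].min()) <= 0:
            raise DataValidationError("trap areas must be positive")
        cnt = self.counts["count"].to_numpy()
        if len(cnt) and (np.any(cnt < 0) or np.any(cnt != np.round(cnt))):
            raise DataValidationError("seed counts must be non-negative integers")
        if len(self.species) and float(self.species["dbh_r"].min()) <= 0:
            raise DataValidationError("reproductive thresholds must be positive")

    # -- species-level accessors -------------------------------------------

    def species_row(self, code: str) -> pd.Series:
        rows = self.species[self.species["code"] == code]
        if len(rows) != 1:
            raise KeyError(f"species {code!r} not found (or duplicated) in metadata")
        return rows.iloc[0]

    def reproductive_trees(self, code: str) -> pd.DataFrame:
        """Conspecific stems at or above the species' reproductive threshold."""
        dbh_r = float(self.species_row(code)["dbh_r"])
        t = self.trees
        return t[(t["species"] == code) & (t["dbh"] >= dbh_r)]

    def trap_counts(self, code: str) -> np.ndarray:
        """Seed counts for one species aligned to ``self.traps`` row order."""
        sub = self.counts[self.counts["species"] == code]
        lookup = dict(zip(sub["trap_id"], sub["count"]))
        return np.array([int(lookup.get(tid, 0)) for tid in self.traps["id"]])

    def species_passing_filter(self, min_seeds: int = 250, min_traps: int = 20) -> list[str]:
        """Species with enough seed rain for inverse modeling.

        Defaults require at least ``min_seeds`` seeds in total, spread over at
        least ``min_traps`` distinct traps.
        """
        out = []
        for code in self.species["code"]:
            n = self.trap_counts(code)
            if n.sum() >= min_seeds and int((n > 0).sum()) >= min_traps:
                out.append(code)
        return out


def read_census(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, [c for c in TREE_COLUMNS if c != "survived"], "census")
    if "survived" in df.columns:
        df["survived"] = df["survived"].astype(bool)
    return df


def read_traps(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "area" not in df.columns:
        df["area"] = 0.5
    _require_columns(df, TRAP_COLUMNS, "traps")
    return df


def read_seed_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, COUNT_COLUMNS, "seed counts")
    return df


def read_species(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, SPECIES_COLUMNS, "species")
    return df
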