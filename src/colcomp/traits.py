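"""Functional-trait preprocessing, PCA and trait-ability correlations.

The trait table holds one row per species: wood density (g cm^-3), seed
mass (g), SLA (cm^2 g^-1), LDMC, leaf area (cm^2), leaf lamina thickness
(cm), leaf lamina density and foliar chlorophyll concentration.  Lamina
density is derived as ``1 / (SLA * thickness)``.  Because trait units are
heterogeneous, PCA runs on standardized (zero-mean, unit-variance) traits,
i.e. on the correlation matrix.  Trait-ability relationships reuse the
paired-bootstrap machinery with the trait values held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import BootstrapDistribution, CorrelationResult, paired_bootstrap_correlation

__all__ = ["leaf_lamina_density", "trait_pca", "trait_ability_correlation", "PCAResult"]


def leaf_lamina_density(sla, thickness):
    """Leaf lamina density ``1 / (SLA * thickness)`` in g cm^-3, with SLA in
    cm^2 g^-1 and thickness in cm."""
    sla = np.asarray(sla, float)
    thickness = np.asarray(thickness, float)
    if np.any(sla <= 0) or np.any(thickness <= 0):
        raise ValueError("SLA and lamina thickness must be strictly positive")
    out = 1.0 / (sla * thickness)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame          # species x components
    loadings: pd.DataFrame        # traits x components, orthonormal columns
    variance_fraction: np.ndarray  # per retained component


def trait_pca(table: pd.DataFrame, n_components: int = 3) -> PCAResult:
    """PCA of the standardized species x trait table.

    Requires at least 3 species and no missing values (no imputation is
    attempted).  Component signs follow the convention that the
    largest-magnitude loading of each component is positive.
    """
    if len(table) < 3:
        raise ValueError("PCA needs at least 3 species")
    if table.isna().any().any():
        bad = list(table.columns[table.isna().any()])
        raise ValueError(f"missing trait values in columns {bad}; no imputation is done")
    X = table.to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = list(table.columns[sd == 0])
        raise ValueError(f"constant trait column(s) {bad} cannot be standardized")
    Z = (X - X.mean(axis=0)) / sd

    n_components = min(n_components, min(Z.shape))
    # SVD of the standardized table: right singular vectors are the loadings.
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    var = s**2 / (len(table) - 1)
    frac = var / var.sum()
    load = Vt.T[:, :n_components]
    scores = U[:, :n_components] * s[:n_components]
    # sign convention: dominant loading entry positive
    for k in range(n_components):
        j = np.argmax(np.abs(load[:, k]))
        if load[j, k] < 0:
            load[:, k] *= -1
            scores[:, k] *= -1
    comps = [f"PC{k+1}" for k in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=table.index, columns=comps),
        loadings=pd.DataFrame(load, index=table.columns, columns=comps),
        variance_fraction=frac[:n_components],
    )


def trait_ability_correlation(
    trait_values: pd.Series,
    ability_boot: dict[str, BootstrapDistribution],
    label: str = "",
    n_draw: int = 1000,
    seed: int = 0,
    method: str = "pearson",
) -> CorrelationResult:
    """Correlation of a fixed per-species trait (or PC score) with a
    bootstrapped ability: draws resample the ability only."""
    fixed = {
        str(sp): BootstrapDistribution(str(sp), np.array([float(v)]))
        for sp, v in trait_values.items()
    }
    return paired_bootstrap_correlation(
        fixed, ability_boot, label=label, n_draw=n_draw, seed=seed, method=method
    )
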