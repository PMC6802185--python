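"""End-to-end trade-off analysis.

Chains the full procedure on one dataset: screen species by seed-rain
sufficiency, fit the four dispersal kernels and select by AIC, convert the
selected fit into colonization ability 1/t (at 5, 10 and 20 cm DBH) and
long-distance dispersal, fit the neighborhood-crowding survival models and
express competitive ability as SOR at the community-wide 97.5th crowding
percentile, propagate uncertainty with the trap and quadrat bootstraps, and
test the cross-species correlations with the paired bootstrap.

A statistically significant negative correlation between 1/t and SOR under
high crowding is the evidence criterion for a competition-colonization
trade-off; correlations of SOR with the two components of colonization
(fecundity and LDD) are reported alongside.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .colonization import colonization_ability, marginal_gap_probability
from .competition import (
    SurvivalFitError,
    crowding_percentile,
    crowding_table,
    fit_survival,
    survival_odds_ratio,
)
from .data import SeedDataset
from .inference import (
    BootstrapDistribution,
    assign_quadrats,
    bootstrap_quadrats,
    bootstrap_seed_traps,
    paired_bootstrap_correlation,
)
from .seed_shadow import FitError, fit_all_families, select_best_kernel

__all__ = ["run_tradeoff_analysis"]


def _sub_seed(root: np.random.SeedSequence, *key: int) -> int:
    """A deterministic 31-bit child seed of the master seed."""
    return int(np.random.SeedSequence(entropy=root.entropy, spawn_key=key).generate_state(1)[0] % (2**31))


def run_tradeoff_analysis(
    dataset: SeedDataset,
    seed: int = 0,
    dbh_values: tuple[float, ...] = (5.0, 10.0, 20.0),
    n_boot: int = 1000,
    n_draw: int = 1000,
    min_seeds: int = 250,
    min_traps: int = 20,
    n_gap_placements: int = 1000,
    gap_placement_seed: int = 0,
    method: str = "pearson",
    crowding: pd.DataFrame | None = None,
) -> dict:
    """Run the full pipeline and return a JSON-serializable report.

    All resampling randomness descends deterministically from ``seed``.  The
    gap-placement set that defines the placement-marginalized ``p_G`` is a
    fixed reference set (``gap_placement_seed``), shared across species and
    bootstrap replicates, so that ``p_G`` is one deterministic estimand
    rather than a per-run Monte Carlo draw.
    """
    root = np.random.SeedSequence(seed)
    placement_seed = gap_placement_seed

    report: dict = {
        "settings": {
            "seed": seed, "n_boot": n_boot, "n_draw": n_draw,
            "dbh_values": list(dbh_values), "min_seeds": min_seeds,
            "min_traps": min_traps, "method": method,
        },
        "species": {},
        "correlations": {},
    }

    # ---- dispersal / colonization ---------------------------------------
    included = dataset.species_passing_filter(min_seeds, min_traps)
    report["included_species"] = included

    fits = {}
    ability_boot: dict[str, dict[str, BootstrapDistribution]] = {}
    for k, code in enumerate(included):
        try:
            best = select_best_kernel(fit_all_families(dataset, code))
        except FitError:
            continue
        fits[code] = best
        p_gap = marginal_gap_probability(
            best.kernel, dataset.plot, n_placements=n_gap_placements, seed=placement_seed
        )
        abilities = {
            f"{d:g}": colonization_ability(best, d, plot=dataset.plot, p_gap=p_gap)
            for d in dbh_values
        }
        ability_boot[code] = bootstrap_seed_traps(
            dataset, code, best, n_boot=n_boot, seed=_sub_seed(root, 1, k),
            dbh_values=dbh_values, n_gap_placements=n_gap_placements,
            placement_seed=placement_seed,
        )
        report["species"][code] = {
            "seed_shadow": best.to_json(),
            "p_gap": p_gap,
            "ldd": abilities[f"{dbh_values[0]:g}"].ldd,
            "inv_t": {d: abilities[d].inv_t for d in abilities},
            "t": {d: abilities[d].t for d in abilities},
            "ability_ci": {
                key: list(dist.ci()) for key, dist in ability_boot[code].items()
            },
        }

    # ---- survival / competition -----------------------------------------
    if crowding is None:
        crowding = crowding_table(dataset.trees, dataset.plot)
    nc_star = crowding_percentile(crowding["nc"], 97.5)
    report["nc_star"] = nc_star
    quadrat = assign_quadrats(dataset.trees, dataset.plot)

    sor_boot: dict[str, dict[str, BootstrapDistribution]] = {}
    for k, code in enumerate(included):
        if code not in fits:
            continue
        m = dataset.trees["species"] == code
        focals = dataset.trees.loc[m, ["dbh", "survived"]].copy()
        focals["nc"] = crowding.loc[m.to_numpy(), "nc"].to_numpy()
        focals["edge_ok"] = crowding.loc[m.to_numpy(), "edge_ok"].to_numpy()
        focals["quadrat"] = quadrat[m.to_numpy()].to_numpy()
        usable = focals[focals["edge_ok"] & focals["nc"].notna()]
        dbh_m = float(dataset.species_row(code)["dbh_m"])
        try:
            sfit = fit_survival(usable, species=code)
            sor_boot[code] = bootstrap_quadrats(
                usable, nc_star, species=code, dbh_values=dbh_values,
                dbh_m=dbh_m, n_boot=n_boot, seed=_sub_seed(root, 2, k),
            )
        except (SurvivalFitError, ValueError):
            continue
        report["species"][code]["survival"] = sfit.to_json()
        report["species"][code]["sor"] = {
            f"{d:g}": survival_odds_ratio(sfit, d, nc_star, None)
            for d in dbh_values if d <= dbh_m
        }
        report["species"][code]["sor_ci"] = {
            key: list(dist.ci()) for key, dist in sor_boot[code].items()
        }

    # ---- cross-species correlations ---------------------------------------
    def extract(boot, key):
        return {sp: d[key] for sp, d in boot.items() if key in d}

    pairs: dict[str, tuple[dict, dict]] = {}
    for i, d in enumerate(dbh_values):
        tag = f"{d:g}"
        pairs[f"inv_t_vs_sor_dbh{tag}"] = (
            extract(ability_boot, f"inv_t_{tag}"), extract(sor_boot, f"sor_{tag}"))
        pairs[f"ldd_vs_sor_dbh{tag}"] = (
            extract(ability_boot, "ldd"), extract(sor_boot, f"sor_{tag}"))
        pairs[f"fecundity_vs_sor_dbh{tag}"] = (
            extract(ability_boot, "beta"), extract(sor_boot, f"sor_{tag}"))
        pairs[f"inv_t_vs_fecundity_dbh{tag}"] = (
            extract(ability_boot, f"inv_t_{tag}"), extract(ability_boot, "beta"))
        pairs[f"inv_t_vs_ldd_dbh{tag}"] = (
            extract(ability_boot, f"inv_t_{tag}"), extract(ability_boot, "ldd"))

    tradeoff = False
    for j, (label, (ba, bb)) in enumerate(sorted(pairs.items())):
        try:
            res = paired_bootstrap_correlation(
                ba, bb, label=label, n_draw=n_draw,
                seed=_sub_seed(root, 3, j), method=method,
            )
        except ValueError:
            continue
        report["correlations"][label] = res.to_json()
        if label.startswith("inv_t_vs_sor") and res.significant and res.r < 0:
            tradeoff = True

    report["tradeoff_detected"] = tradeoff
    report["_ability_boot"] = ability_boot   # non-serialized extras for reuse
    report["_sor_boot"] = sor_boot
    report["_fits"] = fits
    return report


def report_to_json(report: dict) -> dict:
    """Strip the in-memory extras, leaving the serializable report."""
    return {k: v for k, v in report.items() if not k.startswith("_")}
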