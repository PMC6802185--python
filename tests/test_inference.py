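"""Bootstrap machinery and the paired-bootstrap correlation test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from colcomp.inference import (
    BootstrapDistribution,
    CorrelationResult,
    assign_quadrats,
    bootstrap_quadrats,
    bootstrap_seed_traps,
    paired_bootstrap_correlation,
)


def dist(values, label="q"):
    return BootstrapDistribution(label, np.asarray(values, float))


class TestBootstrapDistribution:
    def test_mean_and_percentile_interval(self):
        vals = np.arange(1.0, 1001.0)
        d = dist(vals)
        assert d.mean == pytest.approx(500.5)
        lo, hi = d.ci()
        assert lo == pytest.approx(np.percentile(vals, 2.5))
        assert hi == pytest.approx(np.percentile(vals, 97.5))

    def test_interval_level(self):
        d = dist(np.arange(1.0, 1001.0))
        lo50, hi50 = d.ci(50.0)
        lo95, hi95 = d.ci(95.0)
        assert lo95 < lo50 < hi50 < hi95


class TestAssignQuadrats:
    def test_grid_ids_row_major(self):
        trees = pd.DataFrame({"x": [25.0, 0.0, 499.9], "y": [45.0, 0.0, 399.9]})
        q = assign_quadrats(trees, (500.0, 400.0))
        # 25 columns of 20 m: (col 1, row 2) -> 51; origin -> 0; far corner
        assert list(q) == [2 * 25 + 1, 0, 19 * 25 + 24]

    def test_right_edge_clamped_into_last_column(self):
        trees = pd.DataFrame({"x": [500.0], "y": [0.0]})
        assert assign_quadrats(trees, (500.0, 400.0)).iloc[0] == 24

    def test_stems_in_same_cell_share_id(self):
        trees = pd.DataFrame({"x": [1.0, 19.0], "y": [1.0, 19.0]})
        q = assign_quadrats(trees, (500.0, 400.0))
        assert q.iloc[0] == q.iloc[1]


class TestSeedTrapBootstrap:
    def test_keys_and_determinism(self, small_community):
        from colcomp.seed_shadow import fit_seed_shadow

        fit = fit_seed_shadow(small_community.dataset, "SP", "negative_exponential")
        kwargs = dict(n_boot=15, seed=5, n_gap_placements=50)
        b1 = bootstrap_seed_traps(small_community.dataset, "SP", fit, **kwargs)
        b2 = bootstrap_seed_traps(small_community.dataset, "SP", fit, **kwargs)
        assert set(b1) == {"beta", "b1", "p_gap", "inv_t_5", "inv_t_10", "inv_t_20", "ldd"}
        for k in b1:
            np.testing.assert_array_equal(b1[k].values, b2[k].values)
            assert np.all(b1[k].values > 0)
            assert len(b1[k].values) == 15

    def test_replicates_scatter_around_the_point_estimate(self, small_community):
        from colcomp.seed_shadow import fit_seed_shadow

        fit = fit_seed_shadow(small_community.dataset, "SP", "negative_exponential")
        boot = bootstrap_seed_traps(
            small_community.dataset, "SP", fit, n_boot=40, seed=2, n_gap_placements=50
        )
        lo, hi = boot["beta"].ci(80.0)
        assert lo < fit.beta < hi
        lo, hi = boot["b1"].ci(80.0)
        assert lo < fit.kernel.params[0] < hi


class TestQuadratBootstrap:
    @staticmethod
    def _focals(n=600, seed=0):
        rng = np.random.default_rng(seed)
        dbh = rng.lognormal(2.0, 0.5, n)
        nc = rng.normal(6.0, 1.5, n)
        p = expit(2.0 + 0.03 * dbh - 0.35 * nc)
        return pd.DataFrame(
            {
                "dbh": dbh,
                "nc": nc,
                "survived": rng.random(n) < p,
                "quadrat": rng.integers(0, 30, n),
            }
        )

    def test_keys_respect_maximum_size_and_are_deterministic(self):
        focals = self._focals()
        kwargs = dict(nc_star=8.0, dbh_m=15.0, n_boot=25, seed=3)
        b1 = bootstrap_quadrats(focals, **kwargs)
        b2 = bootstrap_quadrats(focals, **kwargs)
        assert set(b1) == {"intercept", "coef_dbh", "coef_nc", "sor_5", "sor_10"}
        for k in b1:
            np.testing.assert_array_equal(b1[k].values, b2[k].values)

    def test_sor_replicates_consistent_with_coefficients(self):
        boot = bootstrap_quadrats(self._focals(), nc_star=8.0, n_boot=25, seed=3)
        expect = np.exp(
            boot["intercept"].values
            + 10.0 * boot["coef_dbh"].values
            + 8.0 * boot["coef_nc"].values
        )
        np.testing.assert_allclose(boot["sor_10"].values, expect, rtol=1e-10)

    def test_interval_covers_generating_coefficient(self):
        boot = bootstrap_quadrats(self._focals(), nc_star=8.0, n_boot=60, seed=4)
        lo, hi = boot["coef_nc"].ci()
        assert lo < -0.35 < hi

    def test_single_quadrat_rejected(self):
        focals = self._focals().assign(quadrat=0)
        with pytest.raises(ValueError):
            bootstrap_quadrats(focals, nc_star=8.0, n_boot=5, seed=0)

    def test_missing_quadrat_column_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_quadrats(
                self._focals().drop(columns="quadrat"), nc_star=8.0, n_boot=5, seed=0
            )


class TestPairedBootstrapCorrelation:
    @staticmethod
    def _point_masses(values):
        return {f"s{i}": dist([v]) for i, v in enumerate(values)}

    def test_point_masses_reduce_to_plain_pearson(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=8)
        b = 0.5 * a + rng.normal(size=8)
        res = paired_bootstrap_correlation(
            self._point_masses(a), self._point_masses(b), n_draw=50, seed=0
        )
        assert res.r == pytest.approx(stats.pearsonr(a, b).statistic, rel=1e-12)
        assert res.ci_low == pytest.approx(res.r) and res.ci_high == pytest.approx(res.r)

    def test_perfect_negative_relationship_is_significant(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = paired_bootstrap_correlation(
            self._point_masses(a), self._point_masses(-2 * a), n_draw=20, seed=0
        )
        assert res.r == pytest.approx(-1.0)
        assert res.significant and res.ci_high < 0

    def test_noisy_unrelated_quantities_not_significant(self):
        rng = np.random.default_rng(8)
        boot_a = {f"s{i}": dist(rng.normal(0, 1, 300)) for i in range(6)}
        boot_b = {f"s{i}": dist(rng.normal(0, 1, 300)) for i in range(6)}
        res = paired_bootstrap_correlation(boot_a, boot_b, n_draw=400, seed=1)
        assert res.ci_low < 0 < res.ci_high and not res.significant

    def test_spearman_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=10)
        b = a + 0.1 * rng.normal(size=10)
        r1 = paired_bootstrap_correlation(
            self._point_masses(a), self._point_masses(b), n_draw=10, seed=0, method="spearman"
        ).r
        r2 = paired_bootstrap_correlation(
            self._point_masses(np.exp(a)), self._point_masses(b), n_draw=10, seed=0, method="spearman"
        ).r
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_requires_three_shared_species(self):
        with pytest.raises(ValueError):
            paired_bootstrap_correlation(
                self._point_masses([1.0, 2.0]), self._point_masses([1.0, 2.0])
            )

    def test_only_shared_species_enter(self):
        a = {"s1": dist([1.0]), "s2": dist([2.0]), "s3": dist([3.0]), "only_a": dist([9.0])}
        b = {"s1": dist([1.0]), "s2": dist([2.0]), "s3": dist([3.0]), "only_b": dist([9.0])}
        assert paired_bootstrap_correlation(a, b, n_draw=5, seed=0).n_species == 3

    def test_unknown_method_rejected(self):
        a = self._point_masses([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            paired_bootstrap_correlation(a, a, method="kendall")

    def test_significance_flag_matches_interval(self):
        assert CorrelationResult("x", -0.5, -0.8, -0.1, 5).significant
        assert not CorrelationResult("x", -0.3, -0.7, 0.1, 5).significant
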