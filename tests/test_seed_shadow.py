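"""Seed-shadow likelihood: expected counts, NLL oracle, fitting, AIC."""

import math

import numpy as np
import pytest
from scipy import stats

from colcomp.data import SeedDataset
from colcomp.kernels import FAMILIES, KernelSpec, kernel_density
from colcomp.seed_shadow import (
    FitError,
    SeedShadowFit,
    basal_area,
    expected_counts,
    expected_trap_count,
    fecundity,
    fit_all_families,
    fit_seed_shadow,
    negative_log_likelihood,
    select_best_kernel,
)


class TestFecundity:
    def test_basal_area_of_10cm_stem(self):
        assert basal_area(10.0) == pytest.approx(25 * np.pi, rel=1e-14)

    def test_basal_area_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            basal_area(0.0)

    def test_fecundity_scales_with_beta_and_area(self):
        assert fecundity(2.0, 10.0) == pytest.approx(50 * np.pi, rel=1e-14)

    def test_fecundity_rejects_negative_beta(self):
        with pytest.raises(ValueError):
            fecundity(-1.0, 10.0)


class TestExpectedCounts:
    def test_matches_explicit_double_loop(self, toy_dataset, exp_kernel):
        """Vectorized means equal a literal sum over trees and traps."""
        beta, dbh_r = 3.0, 5.0
        trees, traps = toy_dataset.trees, toy_dataset.traps
        lam = expected_counts(trees, traps, beta, exp_kernel, toy_dataset.years, dbh_r)
        for k in range(len(traps)):
            trap = traps.iloc[k]
            expect = 0.0
            for _, tr in trees.iterrows():
                if tr["dbh"] < dbh_r:
                    continue
                d = math.hypot(tr["x"] - trap["x"], tr["y"] - trap["y"])
                expect += (
                    toy_dataset.years
                    * trap["area"]
                    * beta
                    * math.pi
                    * (tr["dbh"] / 2) ** 2
                    * kernel_density(exp_kernel, d)
                )
            assert lam[k] == pytest.approx(expect, rel=1e-12)

    def test_single_trap_wrapper_agrees(self, toy_dataset, exp_kernel):
        lam = expected_counts(
            toy_dataset.trees, toy_dataset.traps, 3.0, exp_kernel, 10.0, 5.0
        )
        one = expected_trap_count(
            toy_dataset.trees, toy_dataset.traps.iloc[0], 3.0, exp_kernel, 10.0, 5.0
        )
        assert one == pytest.approx(lam[0], rel=1e-14)

    def test_subreproductive_stems_excluded(self, toy_dataset, exp_kernel):
        lam_all = expected_counts(
            toy_dataset.trees, toy_dataset.traps, 3.0, exp_kernel, 10.0, dbh_r=1.0
        )
        lam_r = expected_counts(
            toy_dataset.trees, toy_dataset.traps, 3.0, exp_kernel, 10.0, dbh_r=5.0
        )
        assert np.all(lam_r < lam_all)

    def test_no_reproductive_trees_gives_zero(self, toy_dataset, exp_kernel):
        lam = expected_counts(
            toy_dataset.trees, toy_dataset.traps, 3.0, exp_kernel, 10.0, dbh_r=100.0
        )
        assert np.all(lam == 0.0)


class TestLikelihood:
    def test_matches_scipy_poisson_logpmf(self, toy_dataset):
        """NLL equals minus the sum of independent Poisson log-pmfs."""
        theta = np.array([np.log(0.8), np.log(12.0)])
        nll = negative_log_likelihood(theta, toy_dataset, "AA", "negative_exponential")
        lam = expected_counts(
            toy_dataset.trees,
            toy_dataset.traps,
            0.8,
            KernelSpec("negative_exponential", (12.0,)),
            toy_dataset.years,
            5.0,
        )
        oracle = -stats.poisson.logpmf(toy_dataset.trap_counts("AA"), lam).sum()
        assert nll == pytest.approx(oracle, rel=1e-12)

    def test_nonfinite_theta_penalized(self, toy_dataset):
        assert negative_log_likelihood(
            np.array([np.nan, 0.0]), toy_dataset, "AA", "negative_exponential"
        ) >= 1e11


def _fit_obeys_stationarity(dataset, fit):
    """The reported optimum is a local minimum of the raw NLL."""
    theta = np.concatenate([[np.log(fit.beta)], np.log(fit.kernel.params)])
    f0 = negative_log_likelihood(theta, dataset, fit.species, fit.kernel.family)
    assert f0 == pytest.approx(-fit.log_lik, rel=1e-9)
    for i in range(len(theta)):
        for eps in (-1e-3, 1e-3):
            th = theta.copy()
            th[i] += eps
            assert (
                negative_log_likelihood(th, dataset, fit.species, fit.kernel.family)
                >= f0 - 1e-7
            )


class TestFitting:
    def test_fit_is_local_optimum_of_joint_likelihood(self, small_community):
        fit = fit_seed_shadow(small_community.dataset, "SP", "negative_exponential")
        assert fit.converged
        _fit_obeys_stationarity(small_community.dataset, fit)

    def test_true_family_recovers_parameters_roughly(self, small_community):
        truth = small_community.ground_truth["species"]["SP"]
        fit = fit_seed_shadow(small_community.dataset, "SP", "negative_exponential")
        assert fit.beta == pytest.approx(truth["beta"], rel=0.5)
        assert fit.kernel.params[0] == pytest.approx(truth["kernel"]["params"][0], rel=0.5)

    def test_all_families_fit_and_selection_prefers_lowest_aic(self, small_community):
        fits = fit_all_families(small_community.dataset, "SP")
        assert set(fits) <= set(FAMILIES) and len(fits) >= 3
        best = select_best_kernel(fits)
        assert best.aic == min(f.aic for f in fits.values())

    def test_unknown_family_rejected(self, toy_dataset):
        with pytest.raises(ValueError):
            fit_seed_shadow(toy_dataset, "AA", "gaussian")

    def test_no_reproductive_trees_raises(self, toy_dataset):
        ds = SeedDataset(
            trees=toy_dataset.trees,
            traps=toy_dataset.traps,
            counts=toy_dataset.counts,
            species=toy_dataset.species.assign(dbh_r=[999.0]),
            years=toy_dataset.years,
            plot=toy_dataset.plot,
        )
        with pytest.raises(FitError):
            fit_seed_shadow(ds, "AA", "negative_exponential")


class TestModelSelection:
    @staticmethod
    def _fit(family, log_lik, n_params):
        return SeedShadowFit(
            species="X",
            kernel=KernelSpec(family, (10.0,) if family == "negative_exponential" else (10.0, 1.0)),
            beta=1.0,
            log_lik=log_lik,
            n_params=n_params,
        )

    def test_aic_formula(self):
        f = self._fit("lognormal", -100.0, 3)
        assert f.aic == pytest.approx(206.0)

    def test_lower_aic_wins(self):
        a = self._fit("negative_exponential", -100.0, 2)   # aic 204
        b = self._fit("lognormal", -99.5, 3)               # aic 205
        assert select_best_kernel([a, b]) is a

    def test_exact_tie_goes_to_fewer_parameters(self):
        a = self._fit("negative_exponential", -100.0, 2)   # aic 204
        b = self._fit("lognormal", -99.0, 3)               # aic 204
        assert select_best_kernel([a, b]) is a

    def test_full_tie_goes_to_family_order(self):
        a = self._fit("weibull", -100.0, 3)
        b = self._fit("lognormal", -100.0, 3)
        winner = min(("weibull", "lognormal"), key=FAMILIES.index)
        assert select_best_kernel([a, b]).kernel.family == winner


class TestDatasetValidation:
    def test_species_filter_thresholds(self, toy_dataset):
        assert toy_dataset.species_passing_filter(min_seeds=5, min_traps=3) == ["AA"]
        assert toy_dataset.species_passing_filter(min_seeds=8, min_traps=3) == []
        assert toy_dataset.species_passing_filter(min_seeds=5, min_traps=4) == []

    def test_reproductive_trees_respect_threshold(self, toy_dataset):
        repro = toy_dataset.reproductive_trees("AA")
        assert (repro["dbh"] >= 5.0).all() and len(repro) == 4

    def test_trap_counts_aligned_to_trap_order(self, toy_dataset):
        np.testing.assert_array_equal(toy_dataset.trap_counts("AA"), [4, 1, 2])
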