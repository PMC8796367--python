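import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from pgsmixup.cohort import TraitSpec
from pgsmixup.exceptions import FitError
from pgsmixup.likelihood import (BinnedLikelihood, GaussianLikelihood,
                                 LikelihoodConfig, equal_frequency_bins,
                                 equal_width_bins, fit_binned_likelihood,
                                 fit_gaussian_likelihood, fit_trait_likelihood,
                                 likelihood_from_dict, likelihood_to_dict, llr,
                                 llr_matrix_for_trait)


class TestGaussianFit:
    def test_hand_computed_moments(self):
        lk = fit_gaussian_likelihood([-1, 1], [-2, 2])
        assert lk.mean_provided == pytest.approx(0.0)
        assert lk.mean_permuted == pytest.approx(0.0)
        assert lk.sd_provided == pytest.approx(np.sqrt(2))
        assert lk.sd_permuted == pytest.approx(2 * np.sqrt(2))

    def test_identical_arms_give_identical_parameters(self):
        vals = [0.3, -1.2, 0.8, 2.0]
        lk = fit_gaussian_likelihood(vals, vals)
        assert lk.mean_provided == lk.mean_permuted
        assert lk.sd_provided == lk.sd_permuted

    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        lk = fit_gaussian_likelihood(rng.normal(0, 1, 10_000),
                                     rng.normal(0, 2, 10_000))
        assert lk.sd_provided == pytest.approx(1.0, rel=0.05)
        assert lk.sd_permuted == pytest.approx(2.0, rel=0.05)

    def test_zero_variance_rejected(self):
        with pytest.raises(FitError, match="zero variance"):
            fit_gaussian_likelihood([1.0, 1.0], [0.0, 1.0])


class TestGaussianLLR:
    def test_identical_densities_give_zero(self):
        lk = GaussianLikelihood(0.0, 1.0, 0.0, 1.0)
        assert llr(lk, 0.7) == pytest.approx(0.0)

    @pytest.mark.parametrize("r,expected", [
        (0.0, np.log(0.5)),      # density ratio N(0,2)/N(0,1) at 0
        (2.0, 0.806853),
    ])
    def test_closed_form_values(self, r, expected):
        lk = GaussianLikelihood(0.0, 1.0, 0.0, 2.0)
        assert llr(lk, r) == pytest.approx(expected, abs=1e-6)

    def test_matches_quadratic_closed_form_on_grid(self):
        lk = GaussianLikelihood(0.1, 0.8, 0.5, 2.0)
        grid = np.linspace(-5, 5, 101)
        direct = (np.log(lk.sd_provided / lk.sd_permuted)
                  + (grid - lk.mean_provided) ** 2 / (2 * lk.sd_provided ** 2)
                  - (grid - lk.mean_permuted) ** 2 / (2 * lk.sd_permuted ** 2))
        np.testing.assert_allclose(llr(lk, grid), direct, atol=1e-12)

    def test_gibbs_inequality_by_monte_carlo(self):
        rng = np.random.default_rng(1)
        lk = GaussianLikelihood(0.0, 1.0, 0.0, 2.5)
        assert llr(lk, rng.normal(0, 1.0, 10_000)).mean() < 0
        assert llr(lk, rng.normal(0, 2.5, 10_000)).mean() > 0


class TestEqualWidthBins:
    def test_uniform_two_bin_construction(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 160)
        breaks = equal_width_bins(x, avg_per_bin=80, min_per_bin=10)
        assert len(breaks) == 3
        width = breaks[-1] - breaks[0]
        assert abs(breaks[1] - 0.5) <= width / 4
        counts = np.histogram(x, breaks)[0]
        assert (counts >= 10).all()

    def test_empty_interior_region_pruned(self):
        # two well-separated clusters leave interior bins empty
        x = np.concatenate([np.random.default_rng(3).normal(0, 0.1, 200),
                            np.random.default_rng(4).normal(10, 0.1, 200)])
        breaks = equal_width_bins(x, avg_per_bin=40, min_per_bin=10)
        counts = np.histogram(x, breaks)[0]
        assert (counts >= 10).all()
        assert np.all(np.diff(breaks) > 0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(FitError):
            equal_width_bins(np.arange(15.0), avg_per_bin=10, min_per_bin=10)

    def test_terminal_bins_respect_minimum_with_outliers(self):
        x = np.concatenate([np.random.default_rng(5).normal(0, 1, 300), [50.0]])
        breaks = equal_width_bins(x, avg_per_bin=30, min_per_bin=10)
        counts = np.histogram(x, breaks)[0]
        assert counts[0] >= 10 and counts[-1] >= 10

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(-100, 100), min_size=60, max_size=300, unique=True),
           st.integers(2, 15))
    def test_every_final_bin_meets_minimum(self, values, min_per_bin):
        breaks = equal_width_bins(np.array(values), avg_per_bin=20,
                                  min_per_bin=min_per_bin)
        counts = np.histogram(values, breaks)[0]
        assert (counts >= min_per_bin).all()
        assert np.all(np.diff(breaks) > 0)


class TestEqualFrequencyBins:
    def test_exact_division(self):
        breaks = equal_frequency_bins(np.arange(1.0, 101.0), avg_per_bin=20)
        counts = np.histogram(np.arange(1.0, 101.0), breaks)[0]
        assert len(counts) == 5 and (counts == 20).all()

    def test_remainder_spread_keeps_counts_within_one(self):
        x = np.arange(1.0, 11.0)
        breaks = equal_frequency_bins(x, avg_per_bin=3)
        counts = np.histogram(x, breaks)[0]
        assert len(counts) == 3
        assert counts.max() - counts.min() <= 1

    def test_all_identical_values_collapse_to_one_bin(self):
        breaks = equal_frequency_bins(np.full(50, 3.0), avg_per_bin=10)
        assert len(breaks) == 2

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(-50, 50), min_size=40, max_size=200, unique=True),
           st.integers(5, 20))
    def test_counts_within_one_without_ties(self, values, avg):
        x = np.array(values)
        if len(x) < 2 * avg:
            return
        breaks = equal_frequency_bins(x, avg_per_bin=avg)
        counts = np.histogram(x, breaks)[0]
        assert counts.max() - counts.min() <= 1


class TestBinnedLLR:
    def test_breaks_come_from_provided_arm_only(self):
        rng = np.random.default_rng(6)
        prov = rng.normal(0, 1, 400)
        a = fit_binned_likelihood(prov, rng.normal(0, 1, 400), avg_per_bin=40)
        b = fit_binned_likelihood(prov, rng.normal(5, 3, 400), avg_per_bin=40)
        np.testing.assert_array_equal(a.breaks, b.breaks)

    def test_agrees_with_brute_force_histogram_oracle(self):
        rng = np.random.default_rng(7)
        prov = rng.normal(0, 1, 500)
        perm = rng.normal(1, 2, 2000)
        lk = fit_binned_likelihood(prov, perm, avg_per_bin=50, min_per_bin=10)
        # independent recomputation: clip into bins, count, smooth, log-ratio
        query = rng.normal(0, 2, 200)
        B = len(lk.breaks) - 1
        def mass(arm):
            idx = np.clip(np.searchsorted(lk.breaks, arm, side="right") - 1, 0, B - 1)
            return (np.bincount(idx, minlength=B) + 1) / (len(arm) + B)
        mp, mm = mass(prov), mass(perm)
        qi = np.clip(np.searchsorted(lk.breaks, query, side="right") - 1, 0, B - 1)
        np.testing.assert_allclose(llr(lk, query), np.log(mm[qi] / mp[qi]), atol=1e-9)

    def test_out_of_range_residuals_use_terminal_bins(self):
        rng = np.random.default_rng(8)
        lk = fit_binned_likelihood(rng.normal(0, 1, 300), rng.normal(0, 2, 300),
                                   avg_per_bin=30)
        assert llr(lk, -100.0) == llr(lk, lk.breaks[0])
        assert llr(lk, 100.0) == pytest.approx(llr(lk, lk.breaks[-1] - 1e-9))

    def test_masses_sum_to_one(self):
        rng = np.random.default_rng(9)
        lk = fit_binned_likelihood(rng.normal(0, 1, 300), rng.normal(0, 2, 50),
                                   avg_per_bin=30)
        assert lk.density_provided.sum() == pytest.approx(1.0, abs=1e-9)
        assert lk.density_permuted.sum() == pytest.approx(1.0, abs=1e-9)


class TestPerTraitModels:
    def test_ordinal_trait_gets_one_density_pair_per_category(self, simulated_panel):
        from pgsmixup.mapping import build_residual_matrix
        from pgsmixup.trait_models import fit_trait_model
        cohort, _, traits = simulated_panel
        trait = next(t for t in traits if t.data_type == "ordinal")
        model = fit_trait_model(trait, cohort)
        matrix = build_residual_matrix(model, cohort, permutation_cap=30, seed=1)
        tl = fit_trait_likelihood(trait, matrix, LikelihoodConfig(avg_per_bin=40))
        fitted = {c: m for c, m in tl.per_category.items() if m is not None}
        assert set(tl.per_category) == set(trait.categories)
        assert len(fitted) == 3

    def test_permuted_llrs_exceed_provided_for_informative_binary_trait(
            self, simulated_panel):
        from pgsmixup.mapping import build_residual_matrix
        from pgsmixup.trait_models import fit_trait_model
        cohort, _, traits = simulated_panel
        trait = next(t for t in traits if t.data_type == "binary")
        model = fit_trait_model(trait, cohort)
        matrix = build_residual_matrix(model, cohort, permutation_cap=20, seed=2)
        tl = fit_trait_likelihood(trait, matrix)
        out = llr_matrix_for_trait(tl, matrix)
        assert out.permuted_llr["llr"].mean() > out.provided_llr.mean()

    def test_equal_residuals_give_zero_llrs(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(0, 1, 500)
        lk = fit_gaussian_likelihood(vals, vals)
        assert np.allclose(llr(lk, vals), 0.0)


def test_likelihood_serialization_round_trip():
    rng = np.random.default_rng(11)
    from pgsmixup.likelihood import TraitLikelihood
    binned = fit_binned_likelihood(rng.normal(0, 1, 300), rng.normal(1, 2, 300),
                                   avg_per_bin=30)
    tl = TraitLikelihood(trait="x", kind="single", model=binned)
    back = likelihood_from_dict(likelihood_to_dict(tl))
    np.testing.assert_array_equal(back.model.breaks, binned.breaks)
    np.testing.assert_array_equal(back.model.density_permuted, binned.density_permuted)
    g = TraitLikelihood(trait="y", kind="single",
                        model=GaussianLikelihood(0.0, 1.0, 0.5, 2.0))
    gb = likelihood_from_dict(likelihood_to_dict(g))
    assert gb.model == g.model
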