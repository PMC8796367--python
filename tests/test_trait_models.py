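import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from pgsmixup.cohort import TraitSpec, build_cohort, validate_cohort
from pgsmixup.exceptions import ComputationError, FitError
from pgsmixup.trait_models import (TraitModel, deviance_residual,
                                   fit_trait_model, load_models,
                                   ordinal_deviance_residual, save_models)

from conftest import make_cohort


class TestDevianceResidual:
    @pytest.mark.parametrize("p,expected", [
        (1.0, 0.0),
        (0.5, 1.177410),            # sqrt(2 ln 2)
        (np.exp(-2.0), 2.0),        # sqrt(-2 * -2)
    ])
    def test_closed_form_values(self, p, expected):
        assert deviance_residual(p) == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.0001])
    def test_domain_errors(self, p):
        with pytest.raises(ComputationError):
            deviance_residual(p)

    def test_matches_direct_evaluation_on_grid(self):
        grid = np.linspace(1e-6, 1.0, 2001)
        np.testing.assert_allclose(deviance_residual(grid),
                                   np.sqrt(-2.0 * np.log(grid)), atol=1e-12)

    def test_strictly_decreasing(self):
        grid = np.linspace(0.01, 1.0, 500)
        assert np.all(np.diff(deviance_residual(grid)) < 0)


def _manual_logistic(intercept=0.0, beta=0.0):
    return TraitModel(
        trait=TraitSpec(name="b", data_type="binary"),
        model_family="logistic",
        coefficients={"intercept": intercept, "pgs": beta, "age": 0.0,
                      "sex": 0.0, "age_x_sex": 0.0},
        age_center=50.0, fit_n=100,
    )


class TestResiduals:
    def test_linear_identity_prediction_gives_zero(self):
        model = TraitModel(
            trait=TraitSpec(name="h", data_type="quantitative"),
            model_family="linear",
            coefficients={"intercept": 0.0, "pgs": 1.0, "age": 0.0,
                          "sex": 0.0, "age_x_sex": 0.0},
            age_center=50.0, fit_n=100,
        )
        assert model.residual(5.0, 5.0, 50.0, 0.0) == pytest.approx(0.0)

    def test_logistic_residual_at_half_probability(self):
        model = _manual_logistic()  # P(Y=1) = 0.5 everywhere
        assert model.residual(1.0, 0.0, 50.0, 0.0) == pytest.approx(1.177410, abs=1e-6)

    def test_logistic_residual_zero_at_certain_prediction(self):
        model = _manual_logistic(intercept=40.0)  # P(Y=1) ~ 1
        assert model.residual(1.0, 0.0, 50.0, 0.0) == pytest.approx(0.0, abs=1e-6)

    def test_signed_residual_sign_convention(self):
        model = _manual_logistic()
        assert model.signed_residual(1.0, 0.0, 50.0, 0.0) > 0
        assert model.signed_residual(0.0, 0.0, 50.0, 0.0) < 0

    def test_probability_floor_keeps_residual_finite(self):
        model = _manual_logistic(intercept=80.0)  # P(Y=0) underflows
        r = model.residual(0.0, 0.0, 50.0, 0.0)
        assert np.isfinite(r)
        assert r == pytest.approx(np.sqrt(-2 * np.log(1e-12)))

    def test_uniform_three_category_ordinal_residual(self):
        # thresholds at logit(1/3), logit(2/3) make all categories prob 1/3
        t = np.log(np.array([1 / 3, 2 / 3]) / (1 - np.array([1 / 3, 2 / 3])))
        model = TraitModel(
            trait=TraitSpec(name="hair", data_type="ordinal",
                            categories=("a", "b", "c")),
            model_family="ordered_logistic",
            coefficients={"intercept": 0.0, "pgs": 0.0, "age": 0.0,
                          "sex": 0.0, "age_x_sex": 0.0},
            age_center=50.0, fit_n=100, thresholds=list(t),
        )
        for cat in "abc":
            r = ordinal_deviance_residual(model, cat, 0.0, 50.0, 0.0)
            assert r == pytest.approx(1.482304, abs=1e-6)  # sqrt(-2 ln 1/3)


class TestFitting:
    def test_noise_free_quantitative_recovery(self):
        cohort = make_cohort(n=500, seed=1, beta_pgs=2.0, noise_sd=1e-9)
        trait = TraitSpec(name="height", data_type="quantitative")
        validate_cohort(cohort, [trait])
        model = fit_trait_model(trait, cohort)
        assert model.coefficients["pgs"] == pytest.approx(2.0, abs=1e-6)

    def test_training_residuals_mean_zero(self):
        cohort = make_cohort(n=500, seed=2, beta_pgs=1.0, noise_sd=1.0)
        trait = TraitSpec(name="height", data_type="quantitative")
        validate_cohort(cohort, [trait])
        model = fit_trait_model(trait, cohort)
        sex = (cohort.reported_sex == "male").to_numpy(float)
        res = model.residual(cohort.phenotypes["height"].to_numpy(),
                             cohort.pgs["height"].to_numpy(),
                             cohort.age.to_numpy(), sex)
        assert abs(res.mean()) < 1e-8

    def test_too_few_samples_raises_named_error(self):
        cohort = make_cohort(n=50, seed=3)
        trait = TraitSpec(name="height", data_type="quantitative")
        validate_cohort(cohort, [trait])
        with pytest.raises(FitError, match="height"):
            fit_trait_model(trait, cohort)

    def test_null_binary_weight_within_3_se(self):
        rng = np.random.default_rng(7)
        n = 2000
        pgs = rng.standard_normal(n)
        y = (rng.random(n) < 0.4).astype(float)  # independent of PGS
        age = rng.uniform(20, 70, n)
        sex = np.where(rng.random(n) < 0.5, "M", "F")
        cohort = build_cohort([f"S{i}" for i in range(n)], age, sex, sex,
                              pd.DataFrame({"t": y}), pd.DataFrame({"t": pgs}))
        trait = TraitSpec(name="t", data_type="binary")
        validate_cohort(cohort, [trait])
        model = fit_trait_model(trait, cohort)
        # independent oracle for the standard error
        male = (cohort.reported_sex == "male").to_numpy(float)
        age_c = age - age.mean()
        X = sm.add_constant(np.column_stack([pgs, age_c, male, age_c * male]))
        se = sm.Logit(y, X).fit(disp=0).bse[1]
        assert abs(model.coefficients["pgs"]) < 3 * se

    def test_ordinal_latent_weight_recovery(self):
        rng = np.random.default_rng(11)
        n = 5000
        pgs = rng.standard_normal(n)
        latent = 1.0 * pgs + rng.logistic(size=n)
        cats = np.array(["low", "mid", "high"], dtype=object)[
            np.searchsorted([-1.0, 1.0], latent)]
        age = rng.uniform(20, 70, n)
        sex = np.where(rng.random(n) < 0.5, "M", "F")
        cohort = build_cohort([f"S{i}" for i in range(n)], age, sex, sex,
                              pd.DataFrame({"hair": cats}),
                              pd.DataFrame({"hair": pgs}))
        trait = TraitSpec(name="hair", data_type="ordinal",
                          categories=("low", "mid", "high"))
        validate_cohort(cohort, [trait])
        model = fit_trait_model(trait, cohort)
        assert model.coefficients["pgs"] == pytest.approx(1.0, rel=0.10)
        assert np.all(np.diff(model.thresholds) > 0)

    def test_correct_pairings_have_smaller_residuals_than_permuted(self):
        cohort = make_cohort(n=2000, seed=13, beta_pgs=1.0, noise_sd=1.0)
        trait = TraitSpec(name="height", data_type="quantitative")
        validate_cohort(cohort, [trait])
        model = fit_trait_model(trait, cohort)
        rng = np.random.default_rng(5)
        sex = (cohort.reported_sex == "male").to_numpy(float)
        y = cohort.phenotypes["height"].to_numpy()
        g = cohort.pgs["height"].to_numpy()
        provided = np.abs(model.residual(y, g, cohort.age.to_numpy(), sex))
        shuffled = rng.permutation(len(g))
        permuted = np.abs(model.residual(y, g[shuffled], cohort.age.to_numpy(), sex))
        p = stats.mannwhitneyu(permuted, provided, alternative="greater").pvalue
        assert p < 0.01


def test_model_json_round_trip(tmp_path, simple_cohort, quantitative_trait):
    model = fit_trait_model(quantitative_trait, simple_cohort)
    save_models([model], None, tmp_path / "model.json")
    (back,), _ = load_models(tmp_path / "model.json")
    assert back.coefficients == model.coefficients
    assert back.age_center == model.age_center
    assert back.trait == model.trait
    assert back.fit_n == model.fit_n
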