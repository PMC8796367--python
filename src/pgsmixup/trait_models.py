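"""Per-trait regression of measured phenotype on polygenic score + covariates.

The regression family follows the trait's data type: linear for quantitative
traits, logistic for binary traits and ordered (proportional-odds) logistic
for ordinal traits.  Covariates are age, sex and their interaction: GWAS
summary statistics are usually corrected for these, so their phenotypic
effects are not carried by the PGS and must be modelled alongside it.

Residuals quantify how badly a phenotype fits a (possibly foreign) genotype:
raw residuals for the linear family, and deviance residuals

    d = sqrt(-2 ln P_obs)

for the logistic families, where ``P_obs`` is the model's predicted
probability of the observed outcome/category.  For binary traits this is the
classic GLM deviance residual (signed by outcome); for ordinal traits the
same magnitude formula is applied to the predicted probability of the
observed category, which reduces exactly to the binary form at K=2.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .cohort import BINARY, MALE, ORDINAL, QUANTITATIVE, CohortTable, TraitSpec
from .exceptions import ComputationError, FitError

logger = logging.getLogger(__name__)

DEFAULT_MIN_TRAINING_N = 100
PROBABILITY_FLOOR = 1e-12

_FAMILY_BY_TYPE = {
    QUANTITATIVE: "linear",
    BINARY: "logistic",
    ORDINAL: "ordered_logistic",
}


def deviance_residual(p_observed):
    """Deviance-residual magnitude sqrt(-2 ln p) for the observed outcome.

    Accepts scalars or arrays with 0 < p <= 1; strictly decreasing in p.
    """
    p = np.asarray(p_observed, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ComputationError("deviance residual requires 0 < p <= 1")
    out = np.sqrt(-2.0 * np.log(p))
    return float(out) if np.ndim(p_observed) == 0 else out


@dataclass
class TraitModel:
    """Fitted regression for one trait.

    ``coefficients`` holds weights for (pgs, age, sex, age_x_sex) plus an
    ``intercept`` for the linear/logistic families; the ordered-logistic
    family carries strictly increasing ``thresholds`` (K-1 of them) instead
    of an intercept.  Age is centred by ``age_center`` before use.
    """

    trait: TraitSpec
    model_family: str
    coefficients: dict
    age_center: float
    fit_n: int
    thresholds: list = field(default_factory=list)
    residual_sd: float | None = None
    probability_floor: float = PROBABILITY_FLOOR

    def __post_init__(self):
        if self.model_family != _FAMILY_BY_TYPE[self.trait.data_type]:
            raise FitError(
                f"trait {self.trait.name!r}: family {self.model_family!r} does "
                f"not match data type {self.trait.data_type!r}"
            )
        if self.model_family == "ordered_logistic":
            t = np.asarray(self.thresholds, dtype=float)
            if len(t) != len(self.trait.categories) - 1 or np.any(np.diff(t) <= 0):
                raise FitError(
                    f"trait {self.trait.name!r}: ordered model requires "
                    f"{len(self.trait.categories) - 1} strictly increasing thresholds"
                )

    @property
    def residual_kind(self) -> str:
        return {"linear": "raw", "logistic": "deviance",
                "ordered_logistic": "ordinal_deviance"}[self.model_family]

    # -- prediction ------------------------------------------------------

    def linear_predictor(self, pgs, age, sex):
        """X @ beta over (pgs, centred age, sex, interaction), no intercept."""
        c = self.coefficients
        age_c = np.asarray(age, dtype=float) - self.age_center
        sex = np.asarray(sex, dtype=float)
        return (c["pgs"] * np.asarray(pgs, dtype=float)
                + c["age"] * age_c + c["sex"] * sex + c["age_x_sex"] * age_c * sex)

    def predict(self, pgs, age, sex):
        """Predicted phenotype (linear), P(Y=1) (logistic) or per-category
        probability matrix of shape (n, K) (ordered logistic)."""
        eta = self.linear_predictor(pgs, age, sex)
        if self.model_family == "linear":
            return self.coefficients["intercept"] + eta
        if self.model_family == "logistic":
            return expit(self.coefficients["intercept"] + eta)
        cuts = np.asarray(self.thresholds, dtype=float)
        cum = expit(cuts[None, :] - np.atleast_1d(eta)[:, None])
        cum = np.hstack([np.zeros((cum.shape[0], 1)), cum, np.ones((cum.shape[0], 1))])
        return np.diff(cum, axis=1)

    def observed_probability(self, phenotype, pgs, age, sex):
        """Model probability of the observed outcome/category (logistic families)."""
        if self.model_family == "logistic":
            p1 = self.predict(pgs, age, sex)
            y = np.asarray(phenotype, dtype=float)
            return np.where(y == 1.0, p1, 1.0 - p1)
        if self.model_family == "ordered_logistic":
            probs = self.predict(np.atleast_1d(pgs), np.atleast_1d(age), np.atleast_1d(sex))
            cats = list(self.trait.categories)
            idx = pd.Categorical(np.atleast_1d(np.asarray(phenotype, dtype=str)),
                                 categories=cats).codes
            if np.any(idx < 0):
                raise ComputationError(
                    f"trait {self.trait.name!r}: observed category outside declared set")
            return probs[np.arange(probs.shape[0]), idx]
        raise ComputationError("observed_probability is defined for logistic families only")

    # -- residuals -------------------------------------------------------

    def residual(self, phenotype, pgs, age, sex):
        """Residual of a phenotype paired with an arbitrary genotype.

        Linear family: observed - predicted (signed).  Logistic families:
        unsigned deviance residual sqrt(-2 ln P_obs); probabilities below
        ``probability_floor`` are clamped (with a warning) to keep the
        residual finite.
        """
        if self.model_family == "linear":
            res = np.asarray(phenotype, dtype=float) - self.predict(pgs, age, sex)
        else:
            p = np.atleast_1d(self.observed_probability(phenotype, pgs, age, sex))
            n_floored = int(np.sum(p < self.probability_floor))
            if n_floored:
                logger.warning(
                    "trait %s: %d predicted probabilities below floor %.0e were clamped",
                    self.trait.name, n_floored, self.probability_floor)
                p = np.maximum(p, self.probability_floor)
            res = deviance_residual(p)
        if not np.all(np.isfinite(res)):
            raise ComputationError(f"trait {self.trait.name!r}: non-finite residual")
        if np.ndim(phenotype) == 0:
            return float(np.atleast_1d(res)[0])
        return np.asarray(res, dtype=float).reshape(np.shape(phenotype))

    def signed_residual(self, phenotype, pgs, age, sex):
        """Residual with the binary-outcome sign convention (Y=0 negative);
        diagnostics only — the likelihood models downstream are sign-agnostic
        for non-continuous traits."""
        res = np.asarray(self.residual(phenotype, pgs, age, sex), dtype=float)
        if self.model_family == "logistic":
            sign = np.where(np.asarray(phenotype, dtype=float) == 1.0, 1.0, -1.0)
            return res * sign
        return res

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "trait": {
                "name": self.trait.name,
                "data_type": self.trait.data_type,
                "categories": list(self.trait.categories) if self.trait.categories else None,
                "pgs_column": self.trait.pgs_column,
                "phenotype_column": self.trait.phenotype_column,
            },
            "model_family": self.model_family,
            "coefficients": self.coefficients,
            "thresholds": list(map(float, self.thresholds)),
            "age_center": self.age_center,
            "fit_n": self.fit_n,
            "residual_sd": self.residual_sd,
            "probability_floor": self.probability_floor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TraitModel":
        t = d["trait"]
        spec = TraitSpec(
            name=t["name"], data_type=t["data_type"],
            categories=tuple(t["categories"]) if t.get("categories") else None,
            pgs_column=t.get("pgs_column"), phenotype_column=t.get("phenotype_column"),
        )
        return cls(
            trait=spec, model_family=d["model_family"],
            coefficients=d["coefficients"], age_center=d["age_center"],
            fit_n=d["fit_n"], thresholds=d.get("thresholds", []),
            residual_sd=d.get("residual_sd"),
            probability_floor=d.get("probability_floor", PROBABILITY_FLOOR),
        )


def ordinal_deviance_residual(model: TraitModel, observed_category, pgs_value, age, sex):
    """Ordinal deviance residual: sqrt(-2 ln P) of the observed category."""
    if model.model_family != "ordered_logistic":
        raise ComputationError("ordinal_deviance_residual requires an ordered-logistic model")
    return model.residual(np.atleast_1d(np.asarray(observed_category, dtype=str)),
                          np.atleast_1d(pgs_value), np.atleast_1d(age), np.atleast_1d(sex))


def _design(cohort: CohortTable, trait: TraitSpec, mask, age_center: float):
    ids = cohort.sample_ids[np.asarray(mask, dtype=bool)]
    pgs = cohort.pgs.loc[ids, trait.pgs_column].to_numpy(dtype=float)
    age_c = cohort.age.loc[ids].to_numpy(dtype=float) - age_center
    sex = (cohort.reported_sex.loc[ids] == MALE).to_numpy(dtype=float)
    X = np.column_stack([pgs, age_c, sex, age_c * sex])
    return ids, X


def fit_trait_model(
    trait: TraitSpec,
    training: CohortTable,
    min_samples: int = DEFAULT_MIN_TRAINING_N,
) -> TraitModel:
    """Fit the trait's regression on the usable training samples.

    Requires :func:`~pgsmixup.cohort.validate_cohort` to have been run on the
    training cohort (it attaches the usable-sample masks).
    """
    if trait.name not in training.usable:
        raise FitError(f"trait {trait.name!r}: cohort not validated (no usable mask)")
    mask = training.usable[trait.name]
    n = int(mask.sum())
    if n < min_samples:
        raise FitError(
            f"trait {trait.name!r}: {n} usable training samples < minimum {min_samples}")

    age_center = float(training.age[mask].mean())
    ids, X = _design(training, trait, mask, age_center)
    pheno = training.phenotypes.loc[ids, trait.phenotype_column]
    names = ["pgs", "age", "sex", "age_x_sex"]

    if trait.data_type == QUANTITATIVE:
        y = pheno.to_numpy(dtype=float)
        res = sm.OLS(y, sm.add_constant(X)).fit()
        coef = dict(zip(["intercept"] + names, map(float, res.params)))
        return TraitModel(trait=trait, model_family="linear", coefficients=coef,
                          age_center=age_center, fit_n=n,
                          residual_sd=float(np.std(res.resid, ddof=X.shape[1] + 1)))

    if trait.data_type == BINARY:
        y = pheno.to_numpy(dtype=float)
        try:
            res = sm.Logit(y, sm.add_constant(X)).fit(disp=0, maxiter=200)
        except Exception as exc:  # separation raises inside statsmodels
            raise FitError(f"trait {trait.name!r}: logistic fit failed: {exc}") from exc
        if not res.mle_retvals.get("converged", False) or not np.all(np.isfinite(res.params)):
            raise FitError(
                f"trait {trait.name!r}: logistic fit did not converge "
                f"(possible separation); |params| max = {np.max(np.abs(res.params)):.3g}")
        coef = dict(zip(["intercept"] + names, map(float, res.params)))
        return TraitModel(trait=trait, model_family="logistic", coefficients=coef,
                          age_center=age_center, fit_n=n)

    # ordinal
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    y = pd.Series(
        pd.Categorical(pheno.astype(str), categories=list(trait.categories), ordered=True),
        index=pheno.index)
    try:
        mod = OrderedModel(y, X, distr="logit")
        res = mod.fit(method="bfgs", disp=0, maxiter=500)
    except Exception as exc:
        raise FitError(f"trait {trait.name!r}: ordered-logistic fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise FitError(f"trait {trait.name!r}: ordered-logistic fit diverged")
    k = X.shape[1]
    coef = dict(zip(names, map(float, res.params[:k])))
    coef["intercept"] = 0.0
    cuts = mod.transform_threshold_params(res.params[k:])[1:-1]  # strip +-inf
    return TraitModel(trait=trait, model_family="ordered_logistic", coefficients=coef,
                      age_center=age_center, fit_n=n, thresholds=list(map(float, cuts)))


def save_models(models: list[TraitModel], likelihoods: dict | None, path) -> None:
    """Write fitted trait models (and optional likelihood models) to JSON."""
    from .likelihood import likelihood_to_dict

    payload = {
        "format": "pgsmixup-model",
        "version": 1,
        "models": [m.to_dict() for m in models],
    }
    if likelihoods is not None:
        payload["likelihoods"] = {
            name: likelihood_to_dict(lk) for name, lk in likelihoods.items()
        }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_models(path) -> tuple[list[TraitModel], dict]:
    from .likelihood import likelihood_from_dict

    payload = json.loads(Path(path).read_text())
    models = [TraitModel.from_dict(d) for d in payload["models"]]
    likelihoods = {
        name: likelihood_from_dict(d)
        for name, d in payload.get("likelihoods", {}).items()
    }
    return models, likelihoods
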