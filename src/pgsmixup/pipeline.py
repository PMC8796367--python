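"""Train/apply orchestration: fit all per-trait models on a clean cohort,
then score an arbitrary cohort for mix-up evidence.

Fitting assumes the training cohort is predominantly correct (the
regressions and likelihood models would be biased by a large mix-up
fraction).  Scoring is completely separable from fitting, so models fitted
on one half of a study can be applied to the other half, or persisted to a
JSON model file and applied later.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .aggregate import (DEFAULT_ALPHA, DEFAULT_MIN_TRAITS_USED,
                        DEFAULT_SEX_ERROR_RATE, TraitSignificance,
                        score_samples, trait_significance)
from .cohort import MALE, CohortTable, TraitSpec, validate_cohort
from .exceptions import FitError, ValidationError
from .likelihood import (LikelihoodConfig, TraitLikelihood,
                         fit_trait_likelihood, llr_matrix_for_trait)
from .mapping import (DEFAULT_PERMUTATION_CAP, build_residual_matrix,
                      sample_permutation_pairs)
from .trait_models import (DEFAULT_MIN_TRAINING_N, TraitModel, fit_trait_model,
                           load_models, save_models)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    min_training_n: int = DEFAULT_MIN_TRAINING_N
    permutation_cap: int = DEFAULT_PERMUTATION_CAP
    likelihood: LikelihoodConfig = field(default_factory=LikelihoodConfig)
    alpha: float = DEFAULT_ALPHA
    sex_error_rate: float = DEFAULT_SEX_ERROR_RATE
    min_traits_used: int = DEFAULT_MIN_TRAITS_USED
    scaling: str = "row_permuted"


@dataclass
class FittedPipeline:
    """Everything needed to score new samples: regression models,
    likelihood models, the significant-trait selection and the training
    male fraction (used by the sex-check LLR)."""

    models: list
    likelihoods: dict
    significances: list
    male_fraction: float
    config: PipelineConfig = field(default_factory=PipelineConfig)

    @property
    def significant_traits(self) -> list:
        return [s.trait for s in self.significances if s.significant]


def fit_pipeline(train: CohortTable, traits: list[TraitSpec],
                 config: PipelineConfig | None = None, seed: int = 0) -> FittedPipeline:
    """Fit regressions, likelihood models and trait selection on a cohort
    assumed correct.

    Traits that cannot be fitted (too few samples, separation, degenerate
    likelihoods) are skipped with a warning rather than failing the run.
    One permutation pair set is drawn for the whole cohort and shared by
    all traits.
    """
    config = config or PipelineConfig()
    validate_cohort(train, traits)
    rows, cols = sample_permutation_pairs(train.sample_ids, config.permutation_cap, seed)
    pair_ids = (train.sample_ids[rows], train.sample_ids[cols])

    models, likelihoods, significances = [], {}, []
    for trait in traits:
        try:
            model = fit_trait_model(trait, train, min_samples=config.min_training_n)
            matrix = build_residual_matrix(model, train, pairs=pair_ids)
            lk = fit_trait_likelihood(trait, matrix, config.likelihood)
            llrm = llr_matrix_for_trait(lk, matrix)
            sig = trait_significance(llrm, alpha=config.alpha)
        except (FitError, ValidationError) as exc:
            logger.warning("trait %s skipped: %s", trait.name, exc)
            continue
        models.append(model)
        likelihoods[trait.name] = lk
        significances.append(sig)

    if not models:
        raise FitError("no trait could be fitted")
    male_fraction = float((train.reported_sex == MALE).mean())
    return FittedPipeline(models=models, likelihoods=likelihoods,
                          significances=significances,
                          male_fraction=male_fraction, config=config)


def score_cohort(fitted: FittedPipeline, cohort: CohortTable,
                 seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a cohort with a fitted pipeline.

    Returns ``(scores, permuted_scores)`` as produced by
    :func:`pgsmixup.aggregate.score_samples`: per-sample combined mix-up
    evidence plus the permuted-pair score distribution for budgeting.
    """
    config = fitted.config
    traits = [m.trait for m in fitted.models]
    validate_cohort(cohort, traits)
    rows, cols = sample_permutation_pairs(cohort.sample_ids, config.permutation_cap, seed)
    pair_ids = (cohort.sample_ids[rows], cohort.sample_ids[cols])

    sig_names = set(fitted.significant_traits)
    llr_matrices = []
    for model in fitted.models:
        if model.trait.name not in sig_names:
            continue
        matrix = build_residual_matrix(model, cohort, pairs=pair_ids)
        llr_matrices.append(llr_matrix_for_trait(fitted.likelihoods[model.trait.name], matrix))
    if not llr_matrices:
        raise ValidationError("no significant trait available for scoring")

    return score_samples(
        llr_matrices, fitted.significances, cohort,
        male_fraction=fitted.male_fraction,
        error_rate=config.sex_error_rate,
        min_traits_used=config.min_traits_used,
        scaling=config.scaling,
    )


def save_pipeline(fitted: FittedPipeline, path) -> None:
    """Persist the full pipeline (models, likelihoods, trait selection,
    male fraction) to a JSON model file."""
    import json
    from pathlib import Path

    save_models(fitted.models, fitted.likelihoods, path)
    payload = json.loads(Path(path).read_text())
    payload["male_fraction"] = fitted.male_fraction
    payload["significances"] = [
        {"trait": s.trait, "t_statistic": s.t_statistic,
         "p_value": s.p_value, "significant": s.significant}
        for s in fitted.significances
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def load_pipeline(path, config: PipelineConfig | None = None) -> FittedPipeline:
    import json
    from pathlib import Path

    models, likelihoods = load_models(path)
    payload = json.loads(Path(path).read_text())
    significances = [
        TraitSignificance(s["trait"], s["t_statistic"], s["p_value"], s["significant"])
        for s in payload.get("significances", [])
    ] or [TraitSignificance(m.trait.name, float("nan"), float("nan"), True)
          for m in models]
    return FittedPipeline(models=models, likelihoods=likelihoods,
                          significances=significances,
                          male_fraction=payload.get("male_fraction", 0.5),
                          config=config or PipelineConfig())
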