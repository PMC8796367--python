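"""Evaluation protocol: train/test split, induced mix-ups, ROC curves.

The detector's discrimination is measured by fitting on one clean half of a
cohort, deranging the genotypes of a known fraction of the other half, and
asking how well the resulting scores separate the induced mix-ups from the
untouched samples.  Three predictors are compared: the scaled trait-LLR
score alone, the plain sex-concordance check, and their additive
combination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .cohort import UNKNOWN, CohortTable, MixupTruth
from .exceptions import ValidationError
from .likelihood import EQUAL_FREQUENCY, EQUAL_WIDTH, GAUSSIAN, LikelihoodConfig
from .pipeline import PipelineConfig, fit_pipeline, score_cohort
from .simulate import SimulationSpec, induce_mixups, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def split_train_test(cohort: CohortTable, train_fraction: float,
                     seed: int) -> tuple[CohortTable, CohortTable]:
    """Disjoint, exhaustive random partition, reproducible by seed."""
    if not 0 < train_fraction < 1:
        raise ValidationError("train_fraction must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(cohort.n)
    n_train = int(round(cohort.n * train_fraction))
    train_ids = cohort.sample_ids[np.sort(perm[:n_train])]
    test_ids = cohort.sample_ids[np.sort(perm[n_train:])]
    return cohort.subset(train_ids), cohort.subset(test_ids)


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and trapezoidal AUC; ties receive half credit, so the AUC
    equals the Mann-Whitney probability P(score_mixup > score_correct) +
    0.5 P(tie)."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError("ROC requires both classes present")
    fpr, tpr, thresholds = roc_curve(y, s)
    return RocResult(thresholds=thresholds, fpr=fpr, tpr=tpr,
                     auc=float(np.trapezoid(tpr, fpr)))


def sex_check_predictor(cohort: CohortTable) -> pd.Series:
    """1 if reported and genotype-inferred sex disagree, else 0 (0 with a
    flag when the genotype sex is unknown)."""
    unknown = cohort.genotype_sex == UNKNOWN
    if unknown.any():
        logger.info("%d samples have unknown genotype sex; sex check scores 0",
                    int(unknown.sum()))
    score = (cohort.reported_sex != cohort.genotype_sex) & ~unknown
    return score.astype(int)


def evaluate_pipeline(
    spec: SimulationSpec,
    test_mixup_fraction: float = 0.5,
    config: PipelineConfig | None = None,
    train_fraction: float = 0.5,
    predictors: tuple = ("pgs", "sex", "combined"),
) -> dict:
    """Full evaluation on one simulated cohort.

    Simulates a clean cohort from ``spec``, splits it, deranges
    ``test_mixup_fraction`` of the test half, fits on the training half
    only and returns ``{predictor: RocResult}``.  All randomness derives
    from ``spec.seed``.
    """
    clean_spec = SimulationSpec(**{**spec.__dict__, "mixup_fraction": 0.0})
    cohort, _, traits = simulate_cohort(clean_spec)
    seed = spec.seed
    train, test = split_train_test(cohort, train_fraction, seed=seed + 101)
    test, truth = induce_mixups(test, test_mixup_fraction, seed=seed + 202)
    assert not set(train.sample_ids) & set(test.sample_ids)

    fitted = fit_pipeline(train, traits, config=config, seed=seed + 303)
    scores, _ = score_cohort(fitted, test, seed=seed + 404)
    labels = truth.is_mixup.loc[scores.index]

    out = {}
    if "pgs" in predictors:
        out["pgs"] = roc_auc(scores["scaled_llr"], labels)
    if "sex" in predictors:
        sex_scores = sex_check_predictor(test).loc[scores.index]
        out["sex"] = roc_auc(sex_scores, labels)
    if "combined" in predictors:
        out["combined"] = roc_auc(scores["combined_score"], labels)
    return out


def sex_check_experiment(n_samples: int = 2000, male_fraction: float = 0.5,
                         mixup_fraction: float = 0.5, seed: int = 0) -> dict:
    """AUC and zero-false-positive sensitivity of the bare sex check.

    Simulates a balanced (or given-ratio) cohort, deranges the genotype
    side of ``mixup_fraction`` of the samples and scores each by sex
    discordance alone.  With equal numbers of males and females a random
    swap crosses sexes with probability 1/2, so the check catches ~50% of
    mix-ups at zero false positives and its ROC AUC is ~0.75.
    """
    from .simulate import TraitTemplate

    spec = SimulationSpec(
        n_samples=n_samples, male_fraction=male_fraction, seed=seed,
        trait_templates=[TraitTemplate("anchor", "quantitative", 0.3)])
    cohort, _, _ = simulate_cohort(spec)
    mixed, truth = induce_mixups(cohort, mixup_fraction, seed=seed + 1)
    scores = sex_check_predictor(mixed)
    labels = truth.is_mixup
    tpr0 = float(scores[labels].mean())
    false_flags = int(scores[~labels].sum())
    return {"auc": roc_auc(scores, labels).auc,
            "tpr_at_zero_fpr": tpr0,
            "false_positives": false_flags}


def calibration_run(
    spec: SimulationSpec,
    mixup_fraction: float = 0.01,
    max_rate: float = 0.001,
    config: PipelineConfig | None = None,
) -> dict:
    """One end-to-end budgeting experiment with known ground truth.

    Simulates, splits, deranges ``mixup_fraction`` of the test half, then
    follows the operational workflow: remove the samples the sex check
    flags, estimate the residual mix-up rate from the flagged count,
    select the subset whose trait-LLR score keeps the estimated residual
    rate below ``max_rate``, and report the *realized* mix-up fraction in
    that subset.  Budgeting uses the trait-LLR score (the sex check has
    already been spent on the exclusion step).
    """
    from .budget import estimate_mixup_rate, select_passing

    clean_spec = SimulationSpec(**{**spec.__dict__, "mixup_fraction": 0.0})
    cohort, _, traits = simulate_cohort(clean_spec)
    seed = spec.seed
    train, test = split_train_test(cohort, 0.5, seed=seed + 101)
    test, truth = induce_mixups(test, mixup_fraction, seed=seed + 202)
    fitted = fit_pipeline(train, traits, config=config, seed=seed + 303)
    scores, permuted = score_cohort(fitted, test, seed=seed + 404)

    flagged = sex_check_predictor(test).loc[scores.index].astype(bool)
    n_flagged = int(flagged.sum())
    remaining = scores.loc[~flagged].copy()
    est = estimate_mixup_rate(
        swaps_sexcheck=n_flagged, swaps_total=n_flagged,
        male_fraction=fitted.male_fraction, n_remaining=len(remaining))

    remaining["combined_score"] = remaining["scaled_llr"]
    decisions = select_passing(
        remaining, permuted["scaled_llr"].to_numpy(), est.mr_estimated,
        max_rate=max_rate)
    passers = decisions.index[decisions["passes"]]
    is_mixup = truth.is_mixup
    return {
        "mr_estimated": est.mr_estimated,
        "true_rate_remaining": float(is_mixup.loc[remaining.index].mean()),
        "n_pass": int(len(passers)),
        "n_mixups_passing": int(is_mixup.loc[passers].sum()),
        "realized_rate": float(is_mixup.loc[passers].mean()) if len(passers) else 0.0,
    }


def discretization_comparison(
    spec: SimulationSpec,
    avg_bin_sizes: tuple = (20, 30, 50, 80),
    schemes: tuple = (EQUAL_WIDTH, EQUAL_FREQUENCY, GAUSSIAN),
    n_subsets: int = 5,
    mixup_fraction: float = 0.01,
    min_per_bin: int = 10,
) -> pd.DataFrame:
    """Compare likelihood models across binning schemes and bin occupancies.

    For each replicate a fresh cohort is simulated, split, and 1% of the
    test half deranged; every (scheme, avg-per-bin) combination is fitted
    on the same training half and scored on the same test half.  Returns a
    long frame (subset, scheme, avg_per_bin, auc) suitable for an ANOVA.
    """
    records = []
    for subset in range(n_subsets):
        sub_seed = spec.seed + 1000 * (subset + 1)
        clean = SimulationSpec(**{**spec.__dict__, "mixup_fraction": 0.0,
                                  "seed": sub_seed})
        cohort, _, traits = simulate_cohort(clean)
        train, test = split_train_test(cohort, 0.5, seed=sub_seed + 1)
        test, truth = induce_mixups(test, mixup_fraction, seed=sub_seed + 2)
        for scheme in schemes:
            for avg in (avg_bin_sizes if scheme != GAUSSIAN else (None,)):
                lk = LikelihoodConfig(
                    continuous_method=scheme,
                    discrete_scheme=EQUAL_WIDTH if scheme == GAUSSIAN else scheme,
                    avg_per_bin=avg or 80, min_per_bin=min_per_bin)
                cfg = PipelineConfig(likelihood=lk)
                fitted = fit_pipeline(train, traits, config=cfg, seed=sub_seed + 3)
                scores, _ = score_cohort(fitted, test, seed=sub_seed + 4)
                labels = truth.is_mixup.loc[scores.index]
                auc = roc_auc(scores["scaled_llr"], labels).auc
                records.append({"subset": subset, "scheme": scheme,
                                "avg_per_bin": avg, "auc": auc})
    return pd.DataFrame.from_records(records)
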