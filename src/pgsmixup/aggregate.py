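"""Trait selection, LLR summation, per-sample scaling and the sex check.

Traits whose permuted-mapping LLRs do not differ significantly from their
provided-mapping LLRs (Welch t-test, one-sided: permuted > provided) carry
no usable mix-up signal and are dropped.  LLRs of the remaining traits are
summed per sample mapping, and each phenotype row's summed LLR is z-scored
against the summed LLRs of that row's permuted pairings, which puts samples
with different trait availability on a common scale.

The sex-concordance check enters the same log-likelihood-ratio currency:
under a random mix-up the probability that reported and genotype-inferred
sex disagree is 2 f_m (1 - f_m) (f_m = male fraction), while under a correct
mapping a disagreement only arises from assay error at some small rate
epsilon.  The resulting LLR adds directly onto the scaled trait score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, MALE, UNKNOWN
from .exceptions import ValidationError
from .likelihood import LLRMatrix

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_SEX_ERROR_RATE = 0.001
DEFAULT_MIN_TRAITS_USED = 3


@dataclass
class TraitSignificance:
    trait: str
    t_statistic: float
    p_value: float
    significant: bool


@dataclass
class SampleScore:
    """Final per-sample mix-up evidence."""

    sample: str
    summed_llr: float
    scaled_llr: float
    n_traits_used: int
    sex_mismatch: bool | None
    combined_score: float


def trait_significance(llr_matrix: LLRMatrix, alpha: float = DEFAULT_ALPHA) -> TraitSignificance:
    """Welch t-test of permuted vs provided LLRs; significant only in the
    informative direction (permuted mean above provided mean)."""
    prov = llr_matrix.provided_llr.to_numpy()
    perm = llr_matrix.permuted_llr["llr"].to_numpy()
    if len(prov) < 2 or len(perm) < 2:
        raise ValidationError(f"trait {llr_matrix.trait!r}: need >= 2 LLRs per arm")
    if np.var(prov) == 0 and np.var(perm) == 0:
        logger.warning("trait %s: degenerate LLR variance; marked not significant",
                       llr_matrix.trait)
        return TraitSignificance(llr_matrix.trait, float("nan"), float("nan"), False)
    t, p = stats.ttest_ind(perm, prov, equal_var=False, alternative="greater")
    significant = bool(np.isfinite(p) and p < alpha and np.mean(perm) > np.mean(prov))
    return TraitSignificance(llr_matrix.trait, float(t), float(p), significant)


def sum_llrs(per_trait: list[LLRMatrix], significances: list[TraitSignificance]):
    """Sum LLRs over significant traits, per provided sample and per
    permuted pair.

    Samples missing a trait are summed over their available significant
    traits (``n_traits_used`` records how many).  A permuted pair only
    contributes if it was scored in *every* trait used for its phenotype
    row, so provided and permuted sums for a row cover the same trait set.

    Returns ``(sample_sums, permuted_sums)``: a frame indexed by sample with
    ``summed_llr``/``n_traits_used``, and a long frame with columns
    ``phenotype_sample``, ``genotype_sample``, ``summed_llr``.
    """
    sig = {s.trait for s in significances if s.significant}
    used = [m for m in per_trait if m.trait in sig]
    if not used:
        raise ValidationError(
            "no trait reached significance; add traits or raise alpha")

    provided = pd.DataFrame({m.trait: m.provided_llr for m in used})
    sample_sums = pd.DataFrame({
        "summed_llr": provided.sum(axis=1, min_count=1),
        "n_traits_used": provided.notna().sum(axis=1).astype(int),
    })
    sample_sums = sample_sums[sample_sums["n_traits_used"] > 0]

    # accumulate permuted-pair LLRs on integer pair keys (row_pos * n + col_pos);
    # the id universe must cover genotype-side samples with no provided LLR
    ids = provided.index
    for m in used:
        ids = ids.union(pd.Index(m.permuted_llr["genotype_sample"].unique()))
        ids = ids.union(pd.Index(m.permuted_llr["phenotype_sample"].unique()))
    n_ids = len(ids)
    keys_per_trait, llrs_per_trait = [], []
    for m in used:
        rp = ids.get_indexer(m.permuted_llr["phenotype_sample"])
        cp = ids.get_indexer(m.permuted_llr["genotype_sample"])
        keys_per_trait.append(rp.astype(np.int64) * n_ids + cp)
        llrs_per_trait.append(m.permuted_llr["llr"].to_numpy())
    all_keys = np.unique(np.concatenate(keys_per_trait))
    vals = np.full((len(all_keys), len(used)), np.nan)
    for j, (k, v) in enumerate(zip(keys_per_trait, llrs_per_trait)):
        vals[np.searchsorted(all_keys, k), j] = v

    row_pos = all_keys // n_ids
    col_pos = all_keys % n_ids
    keep = pd.Index(ids[row_pos]).isin(sample_sums.index)
    needed = provided.notna().reindex(ids, fill_value=False).to_numpy()[row_pos[keep]]
    v = vals[keep]
    valid = ~(needed & np.isnan(v)).any(axis=1)
    sums = np.where(needed, np.nan_to_num(v), 0.0).sum(axis=1)

    permuted_sums = pd.DataFrame({
        "phenotype_sample": ids[row_pos[keep]][valid],
        "genotype_sample": ids[col_pos[keep]][valid],
        "summed_llr": sums[valid],
    })
    return sample_sums, permuted_sums


def scale_llrs(sample_sums: pd.DataFrame, permuted_sums: pd.DataFrame):
    """z-score each phenotype row's summed LLR against the summed LLRs of
    its own permuted pairings; the permuted sums are scaled with the same
    row statistics.

    Rows with fewer than 2 permuted sums or zero spread pass through
    unscaled with a warning.

    Returns ``(scaled, permuted_scaled)``: a Series per sample and the
    permuted frame with an extra ``scaled_llr`` column.
    """
    codes, uniques = pd.factorize(permuted_sums["phenotype_sample"])
    v = permuted_sums["summed_llr"].to_numpy()
    cnt = np.bincount(codes)
    mean = np.bincount(codes, weights=v) / cnt
    ss = np.bincount(codes, weights=(v - mean[codes]) ** 2)
    sd = np.sqrt(ss / np.maximum(cnt - 1, 1))
    row_stats = pd.DataFrame({"mean": mean, "std": np.where(cnt > 1, sd, np.nan),
                              "count": cnt}, index=pd.Index(uniques))
    stats_al = row_stats.reindex(sample_sums.index)
    bad = (stats_al["count"].fillna(0) < 2) | (stats_al["std"].fillna(0) == 0)
    if bad.any():
        logger.warning("%d rows lack permuted-sum spread; summed LLR passed "
                       "through unscaled", int(bad.sum()))
    scaled = (sample_sums["summed_llr"] - stats_al["mean"]) / stats_al["std"]
    scaled = scaled.where(~bad, sample_sums["summed_llr"]).rename("scaled_llr")

    ps = permuted_sums.merge(row_stats, left_on="phenotype_sample", right_index=True,
                             how="left")
    ok = (ps["count"] >= 2) & (ps["std"] > 0)
    ps["scaled_llr"] = np.where(ok, (ps["summed_llr"] - ps["mean"]) / ps["std"],
                                ps["summed_llr"])
    return scaled, ps[["phenotype_sample", "genotype_sample", "summed_llr", "scaled_llr"]]


def scale_llrs_across_samples(sample_sums: pd.DataFrame, permuted_sums: pd.DataFrame):
    """Alternative scaling for sensitivity analysis: z-score all provided
    sums against their own distribution across samples (one global mean/sd),
    applied to permuted sums as well."""
    m = float(sample_sums["summed_llr"].mean())
    s = float(sample_sums["summed_llr"].std())
    if not s > 0:
        raise ValidationError("zero spread in summed LLRs; cannot scale across samples")
    scaled = ((sample_sums["summed_llr"] - m) / s).rename("scaled_llr")
    ps = permuted_sums.copy()
    ps["scaled_llr"] = (ps["summed_llr"] - m) / s
    return scaled, ps


def sex_llr(reported_sex, genotype_sex, male_fraction: float,
            error_rate: float = DEFAULT_SEX_ERROR_RATE):
    """LLR contribution of the sex-concordance check (vectorized).

    mismatch -> ln(2 f_m (1-f_m) / eps); match -> ln((1 - 2 f_m (1-f_m)) / (1-eps));
    unknown genotype sex -> 0 (check disabled for that sample).
    """
    if not 0 < male_fraction < 1:
        raise ValidationError("male_fraction must be strictly between 0 and 1")
    if not 0 < error_rate < 1:
        raise ValidationError("error_rate must be strictly between 0 and 1")
    rep = np.asarray(reported_sex, dtype=object)
    gen = np.asarray(genotype_sex, dtype=object)
    p_mix = 2.0 * male_fraction * (1.0 - male_fraction)
    val_mismatch = np.log(p_mix / error_rate)
    val_match = np.log((1.0 - p_mix) / (1.0 - error_rate))
    out = np.where(gen == UNKNOWN, 0.0, np.where(rep == gen, val_match, val_mismatch))
    return float(out) if np.ndim(reported_sex) == 0 else out


def combined_score(scaled_llr, sex_llr_value):
    """Additive combination: the sex check and the trait evidence share the
    same log-likelihood-ratio currency."""
    return np.asarray(scaled_llr, dtype=float) + np.asarray(sex_llr_value, dtype=float)


def score_samples(
    per_trait: list[LLRMatrix],
    significances: list[TraitSignificance],
    cohort: CohortTable,
    male_fraction: float | None = None,
    error_rate: float = DEFAULT_SEX_ERROR_RATE,
    min_traits_used: int = DEFAULT_MIN_TRAITS_USED,
    scaling: str = "row_permuted",
):
    """Full aggregation: sum, scale, fold in the sex check.

    Returns ``(scores, permuted_scores)``.  ``scores`` is a frame indexed by
    sample with columns summed_llr, scaled_llr, n_traits_used, sex_mismatch,
    combined_score and insufficient_data (samples below ``min_traits_used``
    keep their values but are flagged rather than silently scored).
    ``permuted_scores`` carries the same combined score for every permuted
    pair (the empirical mix-up score distribution used for budgeting).
    """
    sample_sums, permuted_sums = sum_llrs(per_trait, significances)
    if scaling == "row_permuted":
        scaled, perm_scaled = scale_llrs(sample_sums, permuted_sums)
    elif scaling == "across_samples":
        scaled, perm_scaled = scale_llrs_across_samples(sample_sums, permuted_sums)
    else:
        raise ValidationError(f"unknown scaling {scaling!r}")

    if male_fraction is None:
        male_fraction = float((cohort.reported_sex == MALE).mean())

    ids = sample_sums.index
    rep = cohort.reported_sex.loc[ids]
    gen = cohort.genotype_sex.loc[ids]
    s_llr = sex_llr(rep.to_numpy(), gen.to_numpy(), male_fraction, error_rate)
    mismatch = pd.Series(
        [None if g == UNKNOWN else bool(r != g) for r, g in zip(rep, gen)], index=ids)

    scores = sample_sums.copy()
    scores["scaled_llr"] = scaled
    scores["sex_llr"] = s_llr
    scores["sex_mismatch"] = mismatch
    scores["combined_score"] = combined_score(scaled.to_numpy(), s_llr)
    scores["insufficient_data"] = scores["n_traits_used"] < min_traits_used
    if scores["insufficient_data"].any():
        logger.info("%d samples have fewer than %d usable traits (flagged)",
                    int(scores["insufficient_data"].sum()), min_traits_used)

    # permuted pair: row's reported sex vs the foreign sample's genotype sex
    all_ids = cohort.sample_ids
    rep_row = cohort.reported_sex.to_numpy()[
        all_ids.get_indexer(perm_scaled["phenotype_sample"])]
    gen_col = cohort.genotype_sex.to_numpy()[
        all_ids.get_indexer(perm_scaled["genotype_sample"])]
    perm_sex = sex_llr(rep_row, gen_col, male_fraction, error_rate)
    permuted_scores = perm_scaled.copy()
    permuted_scores["combined_score"] = combined_score(
        perm_scaled["scaled_llr"].to_numpy(), perm_sex)
    return scores, permuted_scores
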