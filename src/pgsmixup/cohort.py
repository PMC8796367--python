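"""Domain types for a genotype-phenotype cohort.

A cohort pairs, per sample, a phenotype record (trait measurements plus the
covariates age and reported sex) with a genotype-side record (one polygenic
score per trait plus the sex inferred from genotype data).  A *sample mix-up*
is a row whose genotype-side record actually belongs to a different
individual; everything downstream in this package exists to find such rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

QUANTITATIVE = "quantitative"
BINARY = "binary"
ORDINAL = "ordinal"
TRAIT_TYPES = (QUANTITATIVE, BINARY, ORDINAL)

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"

_SEX_ALIASES = {
    "m": MALE, "male": MALE, "1": MALE,
    "f": FEMALE, "female": FEMALE, "2": FEMALE,
    "0": UNKNOWN, "u": UNKNOWN, "unknown": UNKNOWN, "na": UNKNOWN, "": UNKNOWN,
}


def normalize_sex(value, allow_unknown: bool = False) -> str:
    """Map the common encodings (M/F, 1/2, Male/Female) onto {male, female}.

    With ``allow_unknown`` (used for genotype-inferred sex) missing markers
    map to ``"unknown"`` instead of raising.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        key = ""
    else:
        key = str(value).strip().lower()
        if key.endswith(".0"):  # numeric 1.0 / 2.0 read from TSV
            key = key[:-2]
    sex = _SEX_ALIASES.get(key)
    if sex is None:
        raise ValidationError(f"unrecognized sex encoding: {value!r}")
    if sex == UNKNOWN and not allow_unknown:
        raise ValidationError(f"sex value {value!r} is missing/unknown where a known sex is required")
    return sex


@dataclass(frozen=True)
class TraitSpec:
    """Metadata for a single trait.

    Parameters
    ----------
    name:
        Unique trait identifier.
    data_type:
        One of ``"quantitative"``, ``"binary"``, ``"ordinal"``.
    categories:
        For ordinal traits, the category labels in increasing order
        (at least 3).  Ignored otherwise.
    pgs_column, phenotype_column:
        Column names in the score and phenotype tables; default to ``name``.
    """

    name: str
    data_type: str
    categories: tuple | None = None
    pgs_column: str | None = None
    phenotype_column: str | None = None

    def __post_init__(self):
        if self.data_type not in TRAIT_TYPES:
            raise ValidationError(
                f"trait {self.name!r}: unknown data_type {self.data_type!r}; "
                f"expected one of {TRAIT_TYPES}"
            )
        if self.data_type == ORDINAL:
            if self.categories is None or len(self.categories) < 3:
                raise ValidationError(
                    f"ordinal trait {self.name!r} needs >= 3 ordered categories"
                )
            object.__setattr__(self, "categories", tuple(str(c) for c in self.categories))
        if self.pgs_column is None:
            object.__setattr__(self, "pgs_column", self.name)
        if self.phenotype_column is None:
            object.__setattr__(self, "phenotype_column", self.name)


def check_unique_trait_names(traits: list[TraitSpec]) -> None:
    names = [t.name for t in traits]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise ValidationError(f"duplicate trait names: {dupes}")


@dataclass
class CohortTable:
    """Aligned per-sample phenotype and genotype-side data.

    All members are indexed by sample ID (``phenotypes`` / ``pgs`` are
    DataFrames with one column per trait).  ``usable`` holds, after
    :func:`validate_cohort`, a boolean Series per trait marking the samples
    with phenotype, PGS, age and reported sex all non-missing.
    """

    sample_ids: pd.Index
    age: pd.Series
    reported_sex: pd.Series
    genotype_sex: pd.Series
    phenotypes: pd.DataFrame
    pgs: pd.DataFrame
    usable: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def subset(self, ids) -> "CohortTable":
        ids = pd.Index(ids)
        return CohortTable(
            sample_ids=ids,
            age=self.age.loc[ids],
            reported_sex=self.reported_sex.loc[ids],
            genotype_sex=self.genotype_sex.loc[ids],
            phenotypes=self.phenotypes.loc[ids],
            pgs=self.pgs.loc[ids],
            usable={k: v.loc[ids] for k, v in self.usable.items()},
        )

    def copy(self) -> "CohortTable":
        return CohortTable(
            sample_ids=self.sample_ids.copy(),
            age=self.age.copy(),
            reported_sex=self.reported_sex.copy(),
            genotype_sex=self.genotype_sex.copy(),
            phenotypes=self.phenotypes.copy(),
            pgs=self.pgs.copy(),
            usable={k: v.copy() for k, v in self.usable.items()},
        )

    def sex_indicator(self) -> pd.Series:
        """Reported sex as 0 (female) / 1 (male), NaN if unknown."""
        return self.reported_sex.map({FEMALE: 0.0, MALE: 1.0})


@dataclass
class MixupTruth:
    """Ground truth of induced mix-ups for simulated cohorts.

    ``source_of_genotype[i]`` names the sample whose genotype-side data row
    ``i`` carries; ``is_mixup`` is true exactly where that differs from the
    row's own ID.
    """

    is_mixup: pd.Series
    source_of_genotype: pd.Series

    def __post_init__(self):
        derived = self.source_of_genotype.index != pd.Index(self.source_of_genotype.values)
        if not np.array_equal(np.asarray(self.is_mixup, dtype=bool), derived):
            raise ValidationError("is_mixup inconsistent with source_of_genotype")
        if sorted(self.source_of_genotype.values) != sorted(self.source_of_genotype.index):
            raise ValidationError("source_of_genotype is not a permutation of sample IDs")


def build_cohort(
    sample_ids,
    age,
    reported_sex,
    genotype_sex,
    phenotypes: pd.DataFrame,
    pgs: pd.DataFrame,
) -> CohortTable:
    """Assemble a CohortTable from aligned arrays, normalizing sex encodings."""
    index = pd.Index(sample_ids, name="sample_id")
    if index.has_duplicates:
        dupes = sorted(index[index.duplicated()].unique().tolist())
        raise ValidationError(f"duplicate sample IDs: {dupes}")
    rep = pd.Series([normalize_sex(v) for v in reported_sex], index=index)
    gen = pd.Series([normalize_sex(v, allow_unknown=True) for v in genotype_sex], index=index)
    return CohortTable(
        sample_ids=index,
        age=pd.Series(np.asarray(age, dtype=float), index=index),
        reported_sex=rep,
        genotype_sex=gen,
        phenotypes=phenotypes.set_axis(index, axis=0),
        pgs=pgs.set_axis(index, axis=0),
    )


def validate_cohort(cohort: CohortTable, traits: list[TraitSpec]) -> CohortTable:
    """Validate a cohort against a trait configuration and attach usable masks.

    Checks sample-ID uniqueness, presence of every declared phenotype/PGS
    column, positivity of recorded ages and membership of ordinal values in
    their declared categories.  A per-trait boolean mask of samples usable
    for modelling (phenotype, PGS, age and reported sex all present) is
    stored on the returned cohort.  Idempotent.
    """
    check_unique_trait_names(traits)
    if cohort.sample_ids.has_duplicates:
        dupes = sorted(cohort.sample_ids[cohort.sample_ids.duplicated()].unique().tolist())
        raise ValidationError(f"duplicate sample IDs: {dupes}")

    finite_age = cohort.age.notna()
    if (cohort.age[finite_age] <= 0).any():
        bad = cohort.age.index[finite_age & (cohort.age <= 0)].tolist()
        raise ValidationError(f"non-positive age for samples: {bad[:5]}")

    covar_ok = finite_age & cohort.reported_sex.isin([MALE, FEMALE])

    for trait in traits:
        if trait.phenotype_column not in cohort.phenotypes.columns:
            raise ValidationError(
                f"phenotype column {trait.phenotype_column!r} for trait "
                f"{trait.name!r} not found"
            )
        if trait.pgs_column not in cohort.pgs.columns:
            raise ValidationError(
                f"PGS column {trait.pgs_column!r} for trait {trait.name!r} not found"
            )
        pheno = cohort.phenotypes[trait.phenotype_column]
        score = cohort.pgs[trait.pgs_column]
        present = pheno.notna() & score.notna()
        if trait.data_type == ORDINAL:
            observed = pheno[present].astype(str)
            bad = sorted(set(observed) - set(trait.categories))
            if bad:
                raise ValidationError(
                    f"ordinal trait {trait.name!r}: values outside declared "
                    f"categories: {bad}"
                )
        elif trait.data_type == BINARY:
            vals = set(pd.unique(pheno[present].astype(float)))
            if not vals <= {0.0, 1.0}:
                raise ValidationError(
                    f"binary trait {trait.name!r}: outcomes must be coded 0/1, "
                    f"got {sorted(vals)[:5]}"
                )
        cohort.usable[trait.name] = (present & covar_ok).rename(trait.name)

    n_excluded = int((~covar_ok).sum())
    if n_excluded:
        logger.info("%d samples lack age or reported sex and are excluded from model fitting", n_excluded)
    return cohort
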