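"""Residuals for provided and permuted genotype-phenotype pairings.

Conceptually this is an n x n matrix over the usable samples of one trait:
row = phenotype side of a sample mapping, column = genotype (PGS) side.  The
main diagonal holds the *provided* mappings as recorded by the study; the
off-diagonal holds *permuted* mappings, which serve as an empirical model of
what residuals look like when a phenotype is paired with the wrong genotype.
The full off-diagonal is quadratic in cohort size, so each row draws at most
``permutation_cap`` distinct foreign genotype columns (the full matrix is
recovered with ``permutation_cap >= n - 1``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import MALE, CohortTable
from .exceptions import ValidationError
from .trait_models import TraitModel

DEFAULT_PERMUTATION_CAP = 1000


@dataclass
class ResidualMatrix:
    """Provided (diagonal) and sampled permuted (off-diagonal) residuals.

    ``permuted`` is a long-format frame with columns ``phenotype_sample``,
    ``genotype_sample`` and ``residual``; no entry pairs a sample with
    itself.  ``row_phenotype`` keeps the observed phenotype value of each
    row (needed downstream to fit per-category likelihoods for ordinal
    traits — the phenotype, and hence the category, is a row property).
    """

    trait: str
    phenotype_samples: pd.Index
    provided: pd.Series
    permuted: pd.DataFrame
    row_phenotype: pd.Series

    def __post_init__(self):
        if (self.permuted["phenotype_sample"] == self.permuted["genotype_sample"]).any():
            raise ValidationError("permuted entries must not pair a sample with itself")

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format dump (trait, phenotype_sample, genotype_sample,
        residual, is_provided) for diagnostics."""
        prov = pd.DataFrame({
            "trait": self.trait,
            "phenotype_sample": self.phenotype_samples,
            "genotype_sample": self.phenotype_samples,
            "residual": self.provided.to_numpy(),
            "is_provided": True,
        })
        perm = self.permuted.assign(trait=self.trait, is_provided=False)
        return pd.concat([prov, perm[prov.columns]], ignore_index=True)


def sample_permutation_pairs(ids: pd.Index, permutation_cap: int, seed: int):
    """Draw, per phenotype row, up to ``permutation_cap`` distinct foreign
    genotype columns without replacement.

    Returns integer arrays (row_idx, col_idx) into ``ids``.  Pairs are drawn
    independently per row, so a genotype column may serve several rows — the
    all-combinations construction has the same property.
    """
    n = len(ids)
    if permutation_cap < 1:
        raise ValidationError("permutation_cap must be >= 1")
    k = min(n - 1, permutation_cap)
    rng = np.random.default_rng(seed)
    rows = np.repeat(np.arange(n), k)
    if k == n - 1:
        cols = np.concatenate([np.delete(np.arange(n), i) for i in range(n)])
    else:
        cols = np.empty(n * k, dtype=np.int64)
        for i in range(n):
            draw = rng.choice(n - 1, size=k, replace=False)
            draw[draw >= i] += 1  # skip the diagonal
            cols[i * k:(i + 1) * k] = draw
    return rows, cols


def build_residual_matrix(
    model: TraitModel,
    cohort: CohortTable,
    permutation_cap: int = DEFAULT_PERMUTATION_CAP,
    seed: int = 0,
    pairs: tuple[np.ndarray, np.ndarray] | None = None,
) -> ResidualMatrix:
    """Compute provided and permuted residuals for one trait.

    ``pairs`` may supply a pre-drawn (row_ids, col_ids) pair set of sample
    IDs (shared across traits by the pipeline so that summed permuted LLRs
    are defined over a common pair set); pairs whose members are unusable
    for this trait are dropped.  Without it, pairs are drawn here from
    ``seed``.
    """
    trait = model.trait
    if trait.name not in cohort.usable:
        raise ValidationError(f"trait {trait.name!r}: cohort not validated")
    mask = cohort.usable[trait.name]
    ids = cohort.sample_ids[np.asarray(mask, dtype=bool)]
    n = len(ids)
    if n < 2:
        raise ValidationError(
            f"trait {trait.name!r}: {n} usable samples; need >= 2 for permutations")

    pheno = cohort.phenotypes.loc[ids, trait.phenotype_column]
    pgs = cohort.pgs.loc[ids, trait.pgs_column].to_numpy(dtype=float)
    age = cohort.age.loc[ids].to_numpy(dtype=float)
    sex = (cohort.reported_sex.loc[ids] == MALE).to_numpy(dtype=float)
    pheno_arr = (pheno.to_numpy(dtype=str) if model.model_family == "ordered_logistic"
                 else pheno.to_numpy(dtype=float))

    provided = model.residual(pheno_arr, pgs, age, sex)

    if pairs is None:
        rows, cols = sample_permutation_pairs(ids, permutation_cap, seed)
    else:
        row_ids, col_ids = pairs
        rpos = ids.get_indexer(row_ids)
        cpos = ids.get_indexer(col_ids)
        keep = (rpos >= 0) & (cpos >= 0)
        rows = rpos[keep]
        cols = cpos[keep]

    perm_res = model.residual(pheno_arr[rows], pgs[cols], age[rows], sex[rows])
    permuted = pd.DataFrame({
        "phenotype_sample": ids[rows],
        "genotype_sample": ids[cols],
        "residual": np.asarray(perm_res, dtype=float),
    })
    return ResidualMatrix(
        trait=trait.name,
        phenotype_samples=ids,
        provided=pd.Series(np.asarray(provided, dtype=float), index=ids, name="residual"),
        permuted=permuted,
        row_phenotype=pheno.astype(str) if trait.data_type != "quantitative" else pheno,
    )
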