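"""File round-tripping: phenotype/PGS TSVs, trait configuration, truth tables.

All tabular interchange uses tab-separated text with a header row; the first
column is the sample ID.  The PGS reader also accepts the PLINK2 ``.sscore``
layout, whose ID column is spelled ``#IID``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .cohort import CohortTable, MixupTruth, TraitSpec, build_cohort, check_unique_trait_names
from .exceptions import ValidationError

MISSING_MARKERS = ["", "NA", "NaN", "nan", "N/A", "null", "None"]

REQUIRED_PHENO_COLUMNS = ("age", "reported_sex", "genotype_sex")


def read_phenotypes(path) -> pd.DataFrame:
    """Read the phenotype/covariate TSV (sample ID first, then `age`,
    `reported_sex`, `genotype_sex` and one column per trait)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=MISSING_MARKERS,
                     keep_default_na=False)
    df = df.set_index(df.columns[0])
    missing = [c for c in REQUIRED_PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"phenotype table {path}: missing columns {missing}")
    return df


def read_pgs(path, score_columns: list[str] | None = None) -> pd.DataFrame:
    """Read a polygenic-score table (generic TSV or PLINK2 .sscore layout)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=MISSING_MARKERS,
                     keep_default_na=False)
    first = df.columns[0]
    if first.startswith("#"):
        df = df.rename(columns={first: first.lstrip("#")})
        first = df.columns[0]
    df = df.set_index(first)
    # drop PLINK bookkeeping columns if present
    df = df.drop(columns=[c for c in ("ALLELE_CT", "NAMED_ALLELE_DOSAGE_SUM") if c in df.columns])
    if score_columns is not None:
        absent = [c for c in score_columns if c not in df.columns]
        if absent:
            raise ValidationError(f"PGS table {path}: missing score columns {absent}")
        df = df[score_columns]
    return df.astype(float)


def read_traits(path) -> list[TraitSpec]:
    """Read trait configuration from a YAML or JSON list of records."""
    text = Path(path).read_text()
    records = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(records, list):
        raise ValidationError(f"trait configuration {path}: expected a list of records")
    traits = []
    for rec in records:
        traits.append(TraitSpec(
            name=rec["name"],
            data_type=rec["data_type"],
            categories=tuple(rec["categories"]) if rec.get("categories") else None,
            pgs_column=rec.get("pgs_column"),
            phenotype_column=rec.get("phenotype_column"),
        ))
    check_unique_trait_names(traits)
    return traits


def write_traits(traits: list[TraitSpec], path) -> None:
    records = []
    for t in traits:
        rec = {"name": t.name, "data_type": t.data_type,
               "pgs_column": t.pgs_column, "phenotype_column": t.phenotype_column}
        if t.categories:
            rec["categories"] = list(t.categories)
        records.append(rec)
    Path(path).write_text(yaml.safe_dump(records, sort_keys=False))


def load_cohort(phenotype_path, pgs_path, traits: list[TraitSpec]) -> CohortTable:
    """Read and align the two input tables on their shared sample IDs."""
    pheno = read_phenotypes(phenotype_path)
    pgs = read_pgs(pgs_path)
    shared = pheno.index.intersection(pgs.index)
    if len(shared) == 0:
        raise ValidationError("no sample IDs shared between phenotype and PGS tables")
    pheno = pheno.loc[shared]
    pgs = pgs.loc[shared]
    trait_cols = [t.phenotype_column for t in traits]
    return build_cohort(
        sample_ids=shared,
        age=pheno["age"],
        reported_sex=pheno["reported_sex"],
        genotype_sex=pheno["genotype_sex"],
        phenotypes=pheno[[c for c in trait_cols if c in pheno.columns]],
        pgs=pgs,
    )


def write_cohort(cohort: CohortTable, phenotype_path, pgs_path) -> None:
    pheno = pd.DataFrame({
        "age": cohort.age,
        "reported_sex": cohort.reported_sex,
        "genotype_sex": cohort.genotype_sex,
    })
    pheno = pd.concat([pheno, cohort.phenotypes], axis=1)
    pheno.index.name = "sample_id"
    pheno.to_csv(phenotype_path, sep="\t")
    out = cohort.pgs.copy()
    out.index.name = "sample_id"
    out.to_csv(pgs_path, sep="\t")


def write_truth(truth: MixupTruth, path) -> None:
    df = pd.DataFrame({
        "is_mixup": truth.is_mixup.astype(int),
        "source_of_genotype": truth.source_of_genotype,
    })
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_truth(path) -> MixupTruth:
    df = pd.read_csv(path, sep="\t", dtype={0: str, "source_of_genotype": str}).set_index("sample_id")
    return MixupTruth(
        is_mixup=df["is_mixup"].astype(bool),
        source_of_genotype=df["source_of_genotype"],
    )
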