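"""Synthetic cohorts with the statistical structure the detector assumes.

The generator draws, per trait, a polygenic score and a latent phenotype
from a joint Gaussian whose cross-trait correlation structure is preserved
(correlated traits are the realistic case; independent traits would
overstate the value of adding more of them).  Each latent phenotype is a
linear combination of its own PGS, age, sex, their interaction and residual
noise, weighted to hit a target PGS-phenotype correlation; binary and
ordinal phenotypes are produced by thresholding the latent value (Gaussian
copula style).  The default 25-trait panel is a synthetic stand-in for a
real biobank panel: mostly quantitative traits with PGS-explained variance
spread over roughly 3%-34%, a few binary conditions and one 3-level ordinal
trait.

Two experiment knobs mirror how detector performance scales:

* ``power_factor`` rescales all PGS-phenotype correlations on the
  atanh-of-r-squared scale: r' = sign(r) * sqrt(tanh(factor * atanh(r^2))),
  which keeps correlations inside (-1, 1) and is the identity at factor 1.
* ``n_copies`` duplicates the trait panel block-diagonally: correlations
  within a copy are preserved, traits in different copies are independent,
  and the covariates (age, sex) are shared.

Ground-truth mix-ups are induced by deranging the genotype-side data (all
PGS columns plus genotype-inferred sex together) within a randomly selected
subset of samples, so every selected sample ends up with another sample's
genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import block_diag

from .cohort import (BINARY, FEMALE, MALE, ORDINAL, QUANTITATIVE, CohortTable,
                     MixupTruth, TraitSpec, build_cohort)
from .exceptions import ValidationError

AGE_RANGE = (18.0, 80.0)


@dataclass(frozen=True)
class TraitTemplate:
    """Generative recipe for one trait.

    ``target_r`` is the intended PGS-phenotype correlation on the latent
    scale (r = sqrt of the PGS-explained variance R^2).  ``thresholds`` are
    latent z-scale cutpoints for binary (one) or ordinal (K-1) traits;
    ``age_beta``/``sex_beta``/``age_sex_beta`` weight standardized age, sex
    and their interaction in the latent phenotype.
    """

    name: str
    data_type: str
    target_r: float
    thresholds: tuple = ()
    categories: tuple = ()
    age_beta: float = 0.0
    sex_beta: float = 0.0
    age_sex_beta: float = 0.0

    def to_spec(self) -> TraitSpec:
        return TraitSpec(name=self.name, data_type=self.data_type,
                         categories=self.categories or None)


@dataclass
class SimulationSpec:
    """Full description of one synthetic cohort."""

    n_samples: int
    trait_templates: list
    cross_trait_correlation: np.ndarray | None = None  # None -> identity
    n_copies: int = 1
    power_factor: float = 1.0
    male_fraction: float = 0.5
    mixup_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.mixup_fraction < 1:
            raise ValidationError("mixup_fraction must lie in [0, 1)")
        if self.power_factor <= 0:
            raise ValidationError("power_factor must be positive")
        if not 0 < self.male_fraction < 1:
            raise ValidationError("male_fraction must lie strictly in (0, 1)")


def scale_pgs_power(correlations, factor: float):
    """Rescale PGS-phenotype correlations on the atanh(r^2) scale.

    r' = sign(r) * sqrt(tanh(factor * atanh(r^2))); identity at factor 1,
    fixed point at r = 0, output stays in (-1, 1).
    """
    if factor <= 0:
        raise ValidationError("factor must be positive")
    r = np.asarray(correlations, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValidationError("|r| must be < 1 (atanh undefined at 1)")
    out = np.sign(r) * np.sqrt(np.tanh(factor * np.arctanh(r ** 2)))
    return float(out) if np.ndim(correlations) == 0 else out


def duplicate_traits(correlation: np.ndarray, n_copies: int) -> np.ndarray:
    """Block-diagonal expansion: within-copy correlations preserved,
    across-copy correlations zero."""
    if n_copies < 1:
        raise ValidationError("n_copies must be >= 1")
    c = np.asarray(correlation, dtype=float)
    expanded = block_diag(*[c] * n_copies)
    _check_psd(expanded)
    return expanded


def _check_psd(corr: np.ndarray) -> None:
    eigmin = float(np.linalg.eigvalsh(corr).min())
    if eigmin < -1e-8:
        raise ValidationError(
            f"correlation matrix is not positive semi-definite (eigenvalue {eigmin:.3g})")


def default_trait_templates() -> list:
    """25-trait synthetic panel: 20 quantitative, 4 binary, 1 ordinal.

    Target explained variances span ~3% to ~34% (r ~ 0.17 to 0.58); the
    names are illustrative only — the panel is a synthetic stand-in, not an
    estimate of any real cohort's correlation structure.
    """
    q = [  # name, R^2, age_beta, sex_beta, age_sex_beta
        ("height", 0.339, 0.05, 0.45, 0.02),
        ("bmi", 0.119, 0.15, 0.05, 0.03),
        ("ldl_cholesterol", 0.15, 0.20, 0.05, 0.05),
        ("hdl_cholesterol", 0.18, 0.10, 0.25, 0.03),
        ("triglycerides", 0.12, 0.15, 0.10, 0.04),
        ("glucose", 0.08, 0.20, 0.05, 0.03),
        ("hba1c", 0.09, 0.22, 0.03, 0.03),
        ("egfr", 0.11, 0.30, 0.05, 0.04),
        ("crp", 0.06, 0.10, 0.08, 0.02),
        ("basophil_count", 0.03, 0.03, 0.03, 0.01),
        ("eosinophil_count", 0.07, 0.04, 0.04, 0.01),
        ("lymphocyte_count", 0.08, 0.08, 0.04, 0.02),
        ("monocyte_count", 0.09, 0.06, 0.06, 0.02),
        ("neutrophil_count", 0.10, 0.05, 0.05, 0.02),
        ("platelet_count", 0.16, 0.08, 0.12, 0.02),
        ("red_cell_count", 0.14, 0.06, 0.20, 0.02),
        ("hemoglobin", 0.13, 0.08, 0.30, 0.03),
        ("heart_rate", 0.05, 0.08, 0.05, 0.02),
        ("fvc", 0.17, 0.25, 0.35, 0.05),
        ("education_years", 0.053, 0.10, 0.02, 0.02),
    ]
    templates = [
        TraitTemplate(name=n, data_type=QUANTITATIVE, target_r=float(np.sqrt(r2)),
                      age_beta=a, sex_beta=s, age_sex_beta=i)
        for n, r2, a, s, i in q
    ]
    b = [  # name, r, prevalence threshold (latent z), age, sex
        ("red_hair", 0.45, 1.64, 0.0, 0.0),     # ~5% prevalence, strongly genetic
        ("asthma", 0.20, 1.04, -0.05, 0.05),    # ~15%
        ("type2_diabetes", 0.22, 1.28, 0.25, 0.05),  # ~10%
        ("eczema", 0.18, 1.04, -0.08, 0.03),
    ]
    templates += [
        TraitTemplate(name=n, data_type=BINARY, target_r=r, thresholds=(t,),
                      age_beta=a, sex_beta=s)
        for n, r, t, a, s in b
    ]
    templates.append(TraitTemplate(
        name="hair_color", data_type=ORDINAL, target_r=0.40,
        thresholds=(-0.3, 0.8), categories=("dark", "brown", "blonde"),
        age_beta=0.0, sex_beta=0.05))
    return templates


_DEFAULT_CLUSTERS = (  # exchangeable rho=0.35 within each cluster
    ("bmi", "ldl_cholesterol", "hdl_cholesterol", "triglycerides", "glucose", "hba1c"),
    ("basophil_count", "eosinophil_count", "lymphocyte_count", "monocyte_count",
     "neutrophil_count", "platelet_count", "red_cell_count", "hemoglobin"),
    ("red_hair", "hair_color"),
)


def default_cross_trait_correlation(templates: list) -> np.ndarray:
    names = [t.name for t in templates]
    corr = np.eye(len(names))
    for cluster in _DEFAULT_CLUSTERS:
        idx = [names.index(n) for n in cluster if n in names]
        for a in idx:
            for b_ in idx:
                if a != b_:
                    corr[a, b_] = 0.35
    _check_psd(corr)
    return corr


def default_simulation_spec(n_samples: int = 5000, seed: int = 0,
                            mixup_fraction: float = 0.0, **kwargs) -> SimulationSpec:
    templates = default_trait_templates()
    return SimulationSpec(
        n_samples=n_samples,
        trait_templates=templates,
        cross_trait_correlation=default_cross_trait_correlation(templates),
        mixup_fraction=mixup_fraction,
        seed=seed,
        **kwargs,
    )


def _expand_copies(templates: list, corr: np.ndarray, n_copies: int):
    if n_copies == 1:
        return list(templates), corr
    expanded = []
    for c in range(1, n_copies + 1):
        for t in templates:
            expanded.append(replace(t, name=f"{t.name}_c{c}" if c > 1 else t.name))
    return expanded, duplicate_traits(corr, n_copies)


def simulate_cohort(spec: SimulationSpec) -> tuple[CohortTable, MixupTruth, list]:
    """Generate a cohort (plus mix-up ground truth and trait specs).

    Reproducible given ``spec.seed``.  PGS-phenotype correlations are first
    rescaled by ``power_factor``, the panel is duplicated ``n_copies``
    times, then PGSs and latent noise are drawn from the cross-trait
    correlation structure and latent phenotypes assembled as

        L = r * PGS + a * age_z + s * sex_z + i * age_z * sex_z + c * noise

    with c chosen so Var(L) = 1, hence corr(PGS, L) = r exactly on the
    latent scale.
    """
    templates = list(spec.trait_templates)
    corr = (np.asarray(spec.cross_trait_correlation, dtype=float)
            if spec.cross_trait_correlation is not None else np.eye(len(templates)))
    if corr.shape != (len(templates), len(templates)):
        raise ValidationError("cross_trait_correlation shape does not match templates")
    if not np.allclose(corr, corr.T) or not np.allclose(np.diag(corr), 1.0):
        raise ValidationError("correlation matrix must be symmetric with unit diagonal")

    templates = [replace(t, target_r=float(scale_pgs_power(t.target_r, spec.power_factor)))
                 for t in templates]
    templates, corr = _expand_copies(templates, corr, spec.n_copies)
    _check_psd(corr)

    rng = np.random.default_rng(spec.seed)
    n, T = spec.n_samples, len(templates)
    L = np.linalg.cholesky(corr + 1e-10 * np.eye(T))
    pgs = rng.standard_normal((n, T)) @ L.T
    noise = rng.standard_normal((n, T)) @ L.T

    age = rng.uniform(*AGE_RANGE, size=n)
    age_z = (age - np.mean(AGE_RANGE)) / ((AGE_RANGE[1] - AGE_RANGE[0]) / np.sqrt(12.0))
    male = rng.random(n) < spec.male_fraction
    f = spec.male_fraction
    sex_z = (male.astype(float) - f) / np.sqrt(f * (1 - f))
    inter_z = age_z * sex_z

    pheno_cols = {}
    for j, t in enumerate(templates):
        covar_var = t.age_beta ** 2 + t.sex_beta ** 2 + t.age_sex_beta ** 2
        resid_var = 1.0 - t.target_r ** 2 - covar_var
        if resid_var < 0:
            raise ValidationError(
                f"trait {t.name!r}: target_r and covariate effects imply "
                f"negative residual variance ({resid_var:.3g})")
        latent = (t.target_r * pgs[:, j] + t.age_beta * age_z + t.sex_beta * sex_z
                  + t.age_sex_beta * inter_z + np.sqrt(resid_var) * noise[:, j])
        if t.data_type == QUANTITATIVE:
            pheno_cols[t.name] = latent
        elif t.data_type == BINARY:
            pheno_cols[t.name] = (latent > t.thresholds[0]).astype(float)
        else:
            idx = np.searchsorted(np.asarray(t.thresholds, dtype=float), latent)
            pheno_cols[t.name] = np.asarray(t.categories, dtype=object)[idx]

    ids = [f"S{i + 1:06d}" for i in range(n)]
    sex_labels = np.where(male, MALE, FEMALE)
    cohort = build_cohort(
        sample_ids=ids,
        age=age,
        reported_sex=sex_labels,
        genotype_sex=sex_labels,
        phenotypes=pd.DataFrame(pheno_cols),
        pgs=pd.DataFrame({t.name: pgs[:, j] for j, t in enumerate(templates)}),
    )
    specs = [t.to_spec() for t in templates]

    if spec.mixup_fraction > 0:
        mixup_seed = int(rng.integers(0, 2 ** 31 - 1))
        cohort, truth = induce_mixups(cohort, spec.mixup_fraction, mixup_seed)
    else:
        truth = MixupTruth(
            is_mixup=pd.Series(False, index=cohort.sample_ids),
            source_of_genotype=pd.Series(list(cohort.sample_ids), index=cohort.sample_ids),
        )
    return cohort, truth, specs


def induce_mixups(cohort: CohortTable, fraction: float, seed: int) -> tuple[CohortTable, MixupTruth]:
    """Derange the genotype-side data of round(n * fraction) samples.

    The selected samples' PGS rows and genotype-inferred sex move together
    (they belong to the same physical genotype), via a single-cycle
    (Sattolo) derangement so every selected sample receives a different
    sample's genotype.  Unselected samples are untouched.
    """
    if not 0 <= fraction < 1:
        raise ValidationError("fraction must lie in [0, 1)")
    n = cohort.n
    k = int(round(n * fraction))
    if k == 0:
        truth = MixupTruth(
            is_mixup=pd.Series(False, index=cohort.sample_ids),
            source_of_genotype=pd.Series(list(cohort.sample_ids), index=cohort.sample_ids),
        )
        return cohort.copy(), truth
    if k == 1:
        raise ValidationError("cannot derange a single sample; need >= 2 mix-ups")

    rng = np.random.default_rng(seed)
    sel = rng.choice(n, size=k, replace=False)
    src = sel.copy()
    for i in range(k - 1, 0, -1):  # Sattolo shuffle: single cycle, no fixed point
        j = rng.integers(0, i)
        src[i], src[j] = src[j], src[i]

    out = cohort.copy()
    pgs_vals = out.pgs.to_numpy().copy()
    pgs_vals[sel] = cohort.pgs.to_numpy()[src]
    out.pgs = pd.DataFrame(pgs_vals, index=out.sample_ids, columns=out.pgs.columns)
    gsex = out.genotype_sex.to_numpy().copy()
    gsex[sel] = cohort.genotype_sex.to_numpy()[src]
    out.genotype_sex = pd.Series(gsex, index=out.sample_ids)

    source = np.array(list(cohort.sample_ids), dtype=object)
    source[sel] = np.array(list(cohort.sample_ids), dtype=object)[src]
    truth = MixupTruth(
        is_mixup=pd.Series(source != np.array(list(cohort.sample_ids)), index=cohort.sample_ids),
        source_of_genotype=pd.Series(source, index=cohort.sample_ids),
    )
    return out, truth
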