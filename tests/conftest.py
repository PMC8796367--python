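import numpy as np
import pandas as pd
import pytest

from pgsmixup.cohort import TraitSpec, build_cohort, validate_cohort
from pgsmixup.simulate import (SimulationSpec, TraitTemplate,
                               default_simulation_spec, simulate_cohort)


@pytest.fixture(scope="session")
def quantitative_trait():
    return TraitSpec(name="height", data_type="quantitative")


def make_cohort(n=200, seed=0, beta_pgs=1.0, noise_sd=1.0, trait="height",
                male_fraction=0.5):
    """Hand-rolled single-quantitative-trait cohort with known generating model."""
    rng = np.random.default_rng(seed)
    pgs = rng.standard_normal(n)
    age = rng.uniform(20, 80, n)
    male = rng.random(n) < male_fraction
    y = beta_pgs * pgs + noise_sd * rng.standard_normal(n)
    sex = np.where(male, "male", "female")
    cohort = build_cohort(
        sample_ids=[f"S{i}" for i in range(n)],
        age=age, reported_sex=sex, genotype_sex=sex,
        phenotypes=pd.DataFrame({trait: y}),
        pgs=pd.DataFrame({trait: pgs}),
    )
    return cohort


@pytest.fixture(scope="session")
def simple_cohort(quantitative_trait):
    cohort = make_cohort(n=400, seed=11, beta_pgs=2.0, noise_sd=0.5)
    return validate_cohort(cohort, [quantitative_trait])


def small_panel_spec(n_samples=1500, seed=0, **kwargs):
    """Compact mixed-type panel for pipeline-level tests."""
    templates = [
        TraitTemplate("height", "quantitative", 0.58, sex_beta=0.45, age_beta=0.05),
        TraitTemplate("bmi", "quantitative", 0.35, age_beta=0.15),
        TraitTemplate("ldl", "quantitative", 0.39, age_beta=0.2),
        TraitTemplate("platelets", "quantitative", 0.40, sex_beta=0.12),
        TraitTemplate("asthma", "binary", 0.20, thresholds=(1.04,)),
        TraitTemplate("hair_color", "ordinal", 0.40, thresholds=(-0.3, 0.8),
                      categories=("dark", "brown", "blonde")),
    ]
    return SimulationSpec(n_samples=n_samples, trait_templates=templates,
                          seed=seed, **kwargs)


@pytest.fixture(scope="session")
def default_spec():
    return default_simulation_spec(n_samples=1500, seed=5)


@pytest.fixture(scope="session")
def simulated_panel():
    """Clean simulated cohort with the compact panel, validated."""
    cohort, truth, traits = simulate_cohort(small_panel_spec(seed=3))
    return validate_cohort(cohort, traits), truth, traits
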