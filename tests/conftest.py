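import numpy as np
import pytest

import sertpk as sp


@pytest.fixture(scope="session")
def final_model() -> sp.PopulationModel:
    """The published final population model (sd interpretation)."""
    return sp.PopulationModel()


@pytest.fixture(scope="session")
def typical_params_70kg() -> sp.StructuralParams:
    return sp.StructuralParams(cl=74.0, v=874.0, ka=0.5)


@pytest.fixture(scope="session")
def small_dataset(final_model):
    """A 30-subject sparse-trough dataset simulated from the final model."""
    spec = sp.CohortSpec(n_subjects=30, troughs_per_subject=2, seed=0)
    cohort = sp.generate_cohort(spec)
    return sp.simulate_tdm(cohort, final_model, spec)


@pytest.fixture(scope="session")
def study_dataset(final_model):
    """A full-size (n=111) study-condition dataset, 2 troughs/subject."""
    spec = sp.CohortSpec(n_subjects=111, troughs_per_subject=2, seed=0)
    cohort = sp.generate_cohort(spec)
    return sp.simulate_tdm(cohort, final_model, spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
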