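import numpy as np
import pytest

from teicopk.cohort import CohortConfig, generate_cohort, simulate_observations
from teicopk.model import CovariateEffect, ModelSpec, ResidualModel, final_model


@pytest.fixture(scope="session")
def published_model():
    return final_model()


@pytest.fixture(scope="session")
def no_bsv_model():
    """Final-model typicals with all variability switched off (sigma tiny)."""
    return ModelSpec(
        theta={"cl": 0.98, "v": 108.69},
        effects=final_model().effects,
        omega2={"cl": 0.0, "v": 0.0},
        residual=ResidualModel("additive", 1e-9),
    )


@pytest.fixture(scope="session")
def rich_dataset(published_model):
    """60 subjects, 8 samples each, simulated from the published model."""
    cfg = CohortConfig(n_subjects=60, sampling_design="rich", seed=101)
    cohort = generate_cohort(cfg)
    return simulate_observations(cohort, published_model, design="rich", seed=102)


def make_cohort(n, seed, **kw):
    return generate_cohort(CohortConfig(n_subjects=n, seed=seed, **kw))


def start_values(effects=(), omega2=None, sigma=0.5):
    """Generic initial values for fitting synthetic teicoplanin data."""
    return ModelSpec(
        theta={"cl": 1.5, "v": 80.0},
        effects=tuple(effects),
        omega2=omega2 if omega2 is not None else {"cl": 0.2, "v": 0.2},
        residual=ResidualModel("additive", sigma),
    )
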