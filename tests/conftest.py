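import numpy as np
import pytest

from nmrmet.config import RunConfig
from nmrmet.simulate import (
    CohortConfig,
    default_templates,
    generate_cohort,
    generate_concentrations,
    signal_catalog,
)


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def catalog(templates):
    return signal_catalog(templates)


@pytest.fixture(scope="session")
def small_truth(templates):
    """A 6-subject cohort with full ground truth (cheap, reused)."""
    cfg = CohortConfig(n_subjects=6, seed=42)
    cohort = generate_cohort(cfg)
    truth = generate_concentrations(cohort, templates, cfg)
    return cfg, cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def run_config():
    return RunConfig(seed=0)
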