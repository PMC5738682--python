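import dataclasses

import numpy as np
import pytest

from methylpanel.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort at the default study conditions."""
    return generate_cohort(seed=1)


@pytest.fixture(scope="session")
def small_config():
    """A reduced cohort for fast unit tests: fewer probes, same tissue arms
    (the 42+42 tissue pairs drive the statistics being tested)."""
    return dataclasses.replace(
        GeneratorConfig(),
        n_probes=400,
        n_diff_probes=24,
        n_age_probes=3,
        arm_sizes={
            "tumor_tissue": 42,
            "normal_tissue": 42,
            "bronchial_biopsy": 8,
            "bronchial_washing": 20,
            "sputum": 6,
            "control_washing": 16,
        },
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
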