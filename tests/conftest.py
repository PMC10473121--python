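import numpy as np
import pandas as pd
import pytest

from methylpanel.simulate import CohortConfig, generate_cohort, generate_reference_panel


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured cohort: all effect classes present."""
    cfg = CohortConfig(
        seed=7, n_pairs=20, n_cpgs=400, n_deconv_cpgs=120,
        n_stable_effect_cpgs=8, n_interaction_cpgs=4, n_crossover_cpgs=4,
        n_aging_cpgs=8, n_clock_cpgs=12,
    )
    matrix, sheet, truth = generate_cohort(cfg)
    return cfg, matrix, sheet, truth


@pytest.fixture(scope="session")
def default_cohort():
    """The generator's default configuration (50 pairs, 2000 CpGs)."""
    cfg = CohortConfig(seed=1)
    matrix, sheet, truth = generate_cohort(cfg)
    return cfg, matrix, sheet, truth


@pytest.fixture(scope="session")
def reference_panel():
    return generate_reference_panel(600, 6, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
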