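import logging

import numpy as np
import pandas as pd
import pytest

from stratmr.simulate import SimulationConfig, simulate_cohort, dosage_columns

# simulation warnings (weak strata etc.) are expected in small test cohorts
logging.getLogger("stratmr").setLevel(logging.ERROR)


def cohort_score(table: pd.DataFrame, config: SimulationConfig) -> np.ndarray:
    """Score individuals with the same weights the simulator used."""
    return table[dosage_columns(table)].to_numpy() @ config.variant_weights


@pytest.fixture(scope="session")
def linear_cohort():
    """One mid-sized cohort with a linear causal effect (theta = 0.1)."""
    config = SimulationConfig(n_individuals=20_000, seed=42)
    return config, simulate_cohort(config)


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort for smoke-level checks."""
    config = SimulationConfig(n_individuals=2_000, seed=7)
    return config, simulate_cohort(config)
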