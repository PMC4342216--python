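import numpy as np
import pandas as pd
import pytest

from fuzzygrade import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Compact but separable cohort for fast pipeline tests."""
    cfg = SimulationConfig(
        n_grade1=20, n_grade3=20, n_grade2=20,
        n_informative=10, n_noise=90, effect=2.5, seed=11,
    )
    return simulate_cohort(cfg) + (cfg,)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the generator's default study conditions."""
    cfg = SimulationConfig(seed=5)
    return simulate_cohort(cfg) + (cfg,)


@pytest.fixture
def toy_training():
    """Tiny hand-built two-class training set: probe A separates, B is noise."""
    expr = pd.DataFrame(
        {
            "s1": [1.0, 5.0],
            "s2": [2.0, 4.0],
            "s3": [1.5, 6.0],
            "s4": [2.5, 5.0],
            "s4b": [1.8, 4.8],
            "s5": [8.0, 5.5],
            "s6": [9.0, 4.5],
            "s7": [8.5, 5.0],
            "s8": [9.5, 6.5],
            "s8b": [8.8, 5.2],
        },
        index=["probeA", "probeB"],
    )
    labels = pd.DataFrame(
        {
            "grade": ["1"] * 5 + ["3"] * 5,
            "er": ["pos"] * 10,
        },
        index=pd.Index(expr.columns, name="sample_id"),
    )
    return expr, labels
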