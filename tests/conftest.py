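from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from ordthresh import (
    FactorSpec,
    PopulationConfig,
    RiskModelConfig,
    compute_risks,
    simulate_cases,
)

REPO_ROOT = Path(__file__).resolve().parent.parent
EXAMPLES = REPO_ROOT / "examples"


@pytest.fixture(scope="session")
def population_config() -> PopulationConfig:
    """Illustrative ocular-hypertension population (matches examples/)."""
    return PopulationConfig(
        factors={
            "age": FactorSpec(55.0, 10.0, 40.0, 80.0),
            "iop": FactorSpec(25.0, 3.0, 24.0, 32.0),
            "cdr": FactorSpec(0.4, 0.2, 0.0, 0.8),
            "psd": FactorSpec(1.9, 0.2, 0.5, 3.0),
            "cct": FactorSpec(573.0, 38.0, 450.0, 700.0),
        },
        p_diabetes=0.10,
        p_female=0.57,
        n_cases=50,
        seed=20100408,
    )


@pytest.fixture(scope="session")
def risk_config() -> RiskModelConfig:
    return RiskModelConfig(
        coefficients={
            "age": 0.02, "iop": 0.12, "cdr": 1.8,
            "psd": 0.4, "cct": -0.012, "diabetes": -0.4,
        },
        intercept=-0.87,
        link="logistic",
    )


@pytest.fixture(scope="session")
def study_cases(population_config) -> pd.DataFrame:
    return simulate_cases(population_config)


@pytest.fixture(scope="session")
def study_risks(study_cases, risk_config) -> np.ndarray:
    return compute_risks(study_cases, risk_config)
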