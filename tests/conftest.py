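import numpy as np
import pandas as pd
import pytest

from qocprofile.config import IndicatorParams, SimulationConfig
from qocprofile.indicators import aggregate, compute_failure_flags
from qocprofile.simulate import simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_facilities=15, volume_range=(150, 400), seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """Moderate synthetic dataset shared across module tests."""
    roster, patients, dispenses, labs, truth = simulate_dataset(small_config)
    return {"roster": roster, "patients": patients, "dispenses": dispenses,
            "labs": labs, "truth": truth, "config": small_config}


@pytest.fixture(scope="session")
def small_flags(small_dataset):
    return compute_failure_flags(
        small_dataset["patients"], small_dataset["dispenses"],
        small_dataset["labs"], IndicatorParams())


@pytest.fixture(scope="session")
def small_aggregates(small_flags, small_dataset):
    aggregates, pi0 = aggregate(small_flags, small_dataset["roster"])
    return aggregates, pi0


def make_units(n, rng=None, **overrides):
    """Minimal covariate frame accepted by the case-mix encoder, with every
    covariate constant unless overridden."""
    rng = rng or np.random.default_rng(0)
    base = {
        "facility_id": np.repeat("F001", n),
        "patient_id": [f"P{i:06d}" for i in range(n)],
        "failures": np.zeros(n, dtype=int),
        "trials": np.ones(n, dtype=int),
        "age_at_diagnosis": np.full(n, 35.0),
        "bmi": np.full(n, 22.0),
        "travel_time_minutes": np.full(n, 60.0),
        "slope": np.full(n, 3.0),
        "gender": np.repeat("female", n),
        "marital_status": np.zeros(n, dtype=int),
        "who_stage": np.ones(n, dtype=int),
        "year_art_start": np.full(n, 2016),
        "department": np.repeat("Ouest", n),
        "category": np.repeat("CAL", n),
        "pregnant_at_art_start": np.zeros(n, dtype=int),
    }
    base.update(overrides)
    return pd.DataFrame(base)
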