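import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ssbtax.hall import bmi_at_times, initialize_state
from ssbtax.population import PopulationConfig, generate_population
from ssbtax.tax import apply_tax

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config():
    return PopulationConfig(n=10_000, seed=12345)


@pytest.fixture(scope="session")
def pop10k(default_config):
    return generate_population(default_config)


@pytest.fixture(scope="session")
def state10k(pop10k):
    return initialize_state(pop10k)


@pytest.fixture(scope="session")
def base_bmi10k(pop10k):
    return (pop10k["weight_kg"] / pop10k["height_m"] ** 2).to_numpy()


@pytest.fixture(scope="session")
def scenario_bmis(pop10k, state10k):
    """BMI arrays at 1 and 10 years for the three headline scenarios.

    Computed once per session; several outcome tests and the acceptance
    checks share these trajectories.
    """
    out = {}
    for name in ("avg10", "peak10", "avg20"):
        deltas = apply_tax(pop10k, name)["delta_kcal"].to_numpy()
        out[name] = bmi_at_times(state10k, deltas, at_years=(1.0, 10.0))
    return out


@pytest.fixture
def reference_adults():
    """Four typical adults spanning sex, age and adiposity."""
    return pd.DataFrame([
        dict(id=0, sex="male", age=40, height_m=1.70, weight_kg=75.0,
             ses="medium", ssb_ml=300.0, svy_weight=1.0),
        dict(id=1, sex="female", age=40, height_m=1.58, weight_kg=68.0,
             ses="medium", ssb_ml=300.0, svy_weight=1.0),
        dict(id=2, sex="male", age=30, height_m=1.75, weight_kg=85.0,
             ses="low", ssb_ml=500.0, svy_weight=1.0),
        dict(id=3, sex="female", age=60, height_m=1.52, weight_kg=62.0,
             ses="high", ssb_ml=100.0, svy_weight=1.0),
    ])


def make_population(rows) -> pd.DataFrame:
    """Small helper to build toy populations from dict fragments."""
    base = dict(sex="female", age=35, height_m=1.60, weight_kg=70.0,
                ses="medium", ssb_ml=200.0, svy_weight=1.0)
    recs = []
    for i, row in enumerate(rows):
        rec = {**base, **row}
        rec.setdefault("id", i)
        recs.append(rec)
    return pd.DataFrame(recs)
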