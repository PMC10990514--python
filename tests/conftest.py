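import numpy as np
import pandas as pd
import pytest

from alert_tuner import (
    FeatureSchema,
    PlantedRule,
    SimulationConfig,
    build_design_matrix,
    derive_outcomes,
    simulate_alert_log,
)


@pytest.fixture(scope="session")
def small_sim():
    """Two BPAs, one planted low-acceptance subgroup, with derived outcomes."""
    config = SimulationConfig(
        n_bpas=2,
        firings_per_bpa=(1500, 1500),
        n_categorical=3,
        categorical_cardinality=4,
        n_numeric=2,
        missingness=0.05,
        planted_rules=(
            PlantedRule(
                "bpa_0", (("cat_0", "c0_v1"),), subgroup_acceptance=0.01, target_coverage=0.12
            ),
        ),
        seed=1234,
    )
    log, truth = simulate_alert_log(config)
    log = derive_outcomes(log)
    return log, truth, config


@pytest.fixture(scope="session")
def small_schema(small_sim):
    log, _, _ = small_sim
    return FeatureSchema.fit(log)


@pytest.fixture(scope="session")
def small_dm(small_sim, small_schema):
    log, _, _ = small_sim
    return build_design_matrix(log, small_schema)


@pytest.fixture(scope="session")
def perfect_log():
    """Deterministic toy: the alert is not accepted exactly when dept = X.

    300 of 3000 firings have dept X; a second categorical and one numeric
    column are uninformative noise.
    """
    rng = np.random.default_rng(99)
    n = 3000
    dept = np.where(np.arange(n) % 10 == 0, "X", rng.choice(["A", "B", "C"], size=n))
    log = pd.DataFrame(
        {
            "bpa_id": "bpa_0",
            "fired_at": pd.date_range("2019-01-01", periods=n, freq="h").astype(str),
            "action": np.where(dept == "X", "Cancel BPA", "single order"),
            "dept": dept,
            "unit": rng.choice(["u1", "u2"], size=n),
            "age": rng.uniform(0, 100, size=n),
        }
    )
    return derive_outcomes(log)


@pytest.fixture(scope="session")
def perfect_dm(perfect_log):
    schema = FeatureSchema.fit(perfect_log)
    return build_design_matrix(perfect_log, schema), schema
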