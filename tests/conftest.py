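import numpy as np
import pandas as pd
import pytest

from dietmsm.simulate import (
    SimulationConfig,
    generate_exclusion_fixture,
    generate_intake_profiles,
    simulate_person_periods,
)


@pytest.fixture(scope="session")
def intake_with_extremes() -> pd.DataFrame:
    return generate_intake_profiles(40, seed=5, include_extreme=True)


@pytest.fixture(scope="session")
def exclusion_fixture():
    return generate_exclusion_fixture(seed=42)


@pytest.fixture(scope="session")
def small_pp():
    """Small simulated person-period table for model-fitting tests."""
    cfg = SimulationConfig(n_subjects=400, seed=3)
    pp, truth = simulate_person_periods(cfg)
    return pp, truth


def toy_person_periods(records) -> pd.DataFrame:
    """Build a minimal person-period table from (id, interval, start, stop,
    A, event, censor) tuples."""
    df = pd.DataFrame(
        records,
        columns=["subject_id", "interval", "start", "stop", "A", "event_allcause", "censor_ltfu"],
    )
    df["event_cancer"] = df["event_allcause"]
    df["score"] = df["A"].astype(float)
    df["lag_quintile"] = df.groupby("subject_id")["A"].shift(1)
    df["lag_score"] = df["lag_quintile"]
    df["bmi"] = 25.0 + df["A"]
    df["energy_kcal"] = 2000.0 + 10 * df["A"]
    return df
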