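import numpy as np
import pandas as pd
import pytest

from ddmtrain import (
    DDMParams,
    FitSettings,
    SyntheticConfig,
    TreatmentConfig,
    generate_study,
    simulate_trials,
)


def signed_sample(params: DDMParams, n: int, seed: int) -> np.ndarray:
    """Simulate a cell and return its sorted signed-RT sample (seconds)."""
    sim = simulate_trials(params, n, seed)
    return np.sort(np.where(sim.upper, 1.0, -1.0) * sim.rt)


@pytest.fixture(scope="session")
def tiny_config() -> SyntheticConfig:
    """A desk-scale study: 3 participants x 4 sessions x 3 tasks x 200 trials."""
    return SyntheticConfig(n_participants=3, n_sessions=4, trials_per_cell=200, seed=11)


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    return generate_study(tiny_config)


@pytest.fixture(scope="session")
def tiny_treatment_config() -> TreatmentConfig:
    """Inclusion thresholds rescaled to the tiny study's cell sizes."""
    return TreatmentConfig(min_trials_per_session=50, min_sessions_per_participant=2)


@pytest.fixture(scope="session")
def quick_settings() -> FitSettings:
    return FitSettings(n_starts=3, seed=5)


def random_trials(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """A random raw trial table for equivalence testing."""
    participants = [f"p{i}" for i in rng.integers(1, 4, n)]
    sessions = rng.integers(1, 4, n)
    tasks = rng.choice(["face", "digit"], n)
    correct = rng.random(n) < 0.85
    # lognormal body plus occasional fast guesses and slow outliers
    rt = np.exp(rng.normal(6.3, 0.35, n)) + 150
    fast = rng.random(n) < 0.05
    rt[fast] = rng.uniform(80, 300, fast.sum())
    slow = rng.random(n) < 0.05
    rt[slow] += rng.uniform(800, 3000, slow.sum())
    df = pd.DataFrame({
        "participant": participants,
        "session": sessions,
        "task": tasks,
        "is_match": rng.random(n) < 0.5,
        "response": "match",
        "correct": correct,
        "rt_ms": rt,
    })
    df["trial"] = df.groupby(["participant", "session", "task"]).cumcount() + 1
    return df
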