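import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from benchrank.data_model import ChallengeData, TaskSlice
from benchrank.synthetic import generate_ideal, generate_random

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def make_slice(columns: dict, task_id: str = "T1", small_better: bool = False) -> TaskSlice:
    """Build a TaskSlice from {algorithm: [per-case values]}."""
    df = pd.DataFrame(columns, dtype=float)
    df.index = [f"c{i + 1}" for i in range(len(df))]
    df.index.name = "case"
    return TaskSlice(task_id, df, small_better)


def make_challenge(tasks: dict, small_better: bool = False) -> ChallengeData:
    """Build ChallengeData from {task: {algorithm: [values]}}."""
    rows = []
    for task, columns in tasks.items():
        for alg, values in columns.items():
            for i, v in enumerate(values):
                rows.append((task, alg, f"c{i + 1}", v))
    df = pd.DataFrame(rows, columns=["task", "algorithm", "case", "value"])
    return ChallengeData(df, small_better=small_better)


@pytest.fixture(scope="session")
def ideal_slice() -> TaskSlice:
    return generate_ideal(n=50, seed=11).task_slice("T1")


@pytest.fixture(scope="session")
def random_slice() -> TaskSlice:
    return generate_random(seed=11).task_slice("T1")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
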