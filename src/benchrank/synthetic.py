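"""Synthetic benchmark challenges for testing and demonstration.

Two canonical single-task scenarios bracket the behaviour of real
challenges:

* the *ideal* challenge — five algorithms draw their per-case metric
  values from fully separated uniform strata ([0.9, 1) for A1 down to
  [0.5, 0.6) for A5), so the true ranking is clear and indisputable
  and every ranking method must recover A1 > A2 > ... > A5;
* the *random* challenge — all five algorithms draw from one identical
  skewed distribution on (0, 1) (a Normal(1.5, 1) sample pushed
  through the logistic function), so any observed difference is due to
  chance alone.

Both emulate a bounded larger-is-better metric such as the Dice
similarity coefficient.  :func:`generate_custom` generalizes them to
multi-task challenges with configurable distributions and missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from benchrank.data_model import ChallengeData

__all__ = ["GeneratorSpec", "generate_ideal", "generate_random", "generate_custom"]

#: uniform strata of the ideal scenario, best algorithm first
IDEAL_STRATA = [(0.9, 1.0), (0.8, 0.9), (0.7, 0.8), (0.6, 0.7), (0.5, 0.6)]


def _records(values: np.ndarray, task: str, algorithms: list[str]) -> pd.DataFrame:
    """Long-format frame from an n_cases x p value matrix."""
    n, p = values.shape
    return pd.DataFrame(
        {
            "task": task,
            "algorithm": np.repeat(algorithms, n),
            "case": np.tile([f"c{i + 1}" for i in range(n)], p),
            "value": values.T.ravel(),
        }
    )


def generate_ideal(n: int = 50, seed: int | None = None) -> ChallengeData:
    """Fully separated single-task challenge (clear true ranking).

    Algorithm ``A_k`` (k = 1..5) draws ``n`` values uniformly from
    [1 - 0.1k, 1.1 - 0.1k), so every A1 value beats every A2 value and
    so on down the strata, for any seed.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    algorithms = [f"A{k}" for k in range(1, 6)]
    values = np.column_stack([rng.uniform(lo, hi, size=n) for lo, hi in IDEAL_STRATA])
    return ChallengeData(_records(values, "T1", algorithms), small_better=False)


def generate_random(seed: int | None = None) -> ChallengeData:
    """Null single-task challenge (differences due to chance alone).

    250 Normal(mean 1.5, variance 1) draws are pushed through the
    logistic function 1/(1 + e^-x), giving a skewed distribution on
    (0, 1), and assigned sequentially (in draw order) to algorithms A1
    to A5 — 50 test cases each.  All algorithms share the identical
    distribution.
    """
    rng = np.random.default_rng(seed)
    draws = rng.normal(loc=1.5, scale=1.0, size=250)
    transformed = 1.0 / (1.0 + np.exp(-draws))
    algorithms = [f"A{k}" for k in range(1, 6)]
    values = transformed.reshape(5, 50).T  # first 50 draws -> A1, next 50 -> A2, ...
    return ChallengeData(_records(values, "T1", algorithms), small_better=False)


@dataclass(frozen=True)
class GeneratorSpec:
    """Configuration for a custom synthetic challenge.

    ``distributions`` lists one per-algorithm sampler spec, each a
    tuple: ``("uniform", lo, hi)``, ``("normal_logistic", mean, sd)``
    (Normal pushed through the logistic function, support (0, 1)) or
    ``("beta", a, b)``.  ``missing_rate`` is the probability that a
    cell is absent before imputation.
    """

    n_cases: int = 50
    distributions: tuple = tuple(("uniform", lo, hi) for lo, hi in IDEAL_STRATA)
    missing_rate: float = 0.0
    algorithms: tuple = field(default=())
    small_better: bool = False

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be at least 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.algorithms and len(self.algorithms) != len(self.distributions):
            raise ValueError("algorithms and distributions differ in length")

    @property
    def algorithm_names(self) -> list[str]:
        if self.algorithms:
            return list(self.algorithms)
        return [f"A{k + 1}" for k in range(len(self.distributions))]


def _sample(dist: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    name = dist[0]
    if name == "uniform":
        return rng.uniform(dist[1], dist[2], size=n)
    if name == "normal_logistic":
        return 1.0 / (1.0 + np.exp(-rng.normal(dist[1], dist[2], size=n)))
    if name == "beta":
        return rng.beta(dist[1], dist[2], size=n)
    raise ValueError(f"unsupported distribution {name!r}")


def generate_custom(
    spec: GeneratorSpec | list[GeneratorSpec],
    tasks: int = 1,
    seed: int | None = None,
) -> ChallengeData:
    """Multi-task synthetic challenge from per-algorithm distributions.

    Either one :class:`GeneratorSpec` replicated over ``tasks`` tasks
    (fresh draws per task) or a list with one spec per task, sharing
    the algorithm count.  Missingness is applied before any imputation:
    each cell is dropped to NaN independently with ``missing_rate``.
    """
    if isinstance(spec, GeneratorSpec):
        specs = [spec] * tasks
    else:
        specs = list(spec)
        if tasks != 1 and tasks != len(specs):
            raise ValueError("tasks count conflicts with the spec list length")
    if not specs:
        raise ValueError("need at least one task spec")
    p = len(specs[0].distributions)
    if any(len(s.distributions) != p for s in specs):
        raise ValueError("all tasks must rank the same number of algorithms")

    rng = np.random.default_rng(seed)
    frames = []
    for t, s in enumerate(specs, start=1):
        values = np.column_stack(
            [_sample(d, s.n_cases, rng) for d in s.distributions]
        )
        if s.missing_rate > 0:
            mask = rng.random(values.shape) < s.missing_rate
            values = np.where(mask, np.nan, values)
        frames.append(_records(values, f"T{t}", s.algorithm_names))
    records = pd.concat(frames, ignore_index=True)
    return ChallengeData(records, small_better=specs[0].small_better)
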