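"""Bootstrap engine for ranking stability.

One bootstrap sample of a task with *n* test cases consists of *n*
cases drawn with replacement from that task; the chosen ranking method
is re-run in full on each of *b* such samples (default b = 1000).  The
resulting replicate rankings feed two complementary summaries:

* per-algorithm rank distributions — rank frequencies, median rank and
  a 95% percentile interval (2.5th to 97.5th percentile), shown in
  blob plots;
* the distribution of Kendall's tau between each replicate ranking and
  the full-data ranking, shown in violin plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from benchrank.data_model import TaskSlice
from benchrank.ranking import Ranking, make_ranker
from benchrank.rank_similarity import UndefinedTauError, kendalls_tau

__all__ = ["BootstrapResult", "bootstrap_rankings", "bootstrap_interval", "tau_to_full"]

#: below this many test cases, bootstrap summaries are flagged as fragile
SMALL_N_CAUTION = 20


@dataclass
class BootstrapResult:
    """Replicate rankings from bootstrap resampling plus summaries.

    Attributes
    ----------
    replicate_ranks:
        b x p DataFrame; row i holds the ranks of all algorithms in
        bootstrap replicate i.
    rank_frequency:
        algorithms x ranks (1..p) count matrix; each row sums to b.
    median_rank, intervals:
        Median and percentile interval of each algorithm's bootstrap
        rank distribution (linear interpolation between order
        statistics).
    tau:
        Kendall's tau of each replicate ranking against the full-data
        ranking; NaN where tau is undefined (fully tied replicate),
        counted in ``n_undefined_tau``.
    small_n_caution:
        True when the task has fewer than 20 test cases — bootstrap
        results from so few cases should be treated with caution.
    """

    task_id: str
    method: str
    b: int
    seed: int
    full_ranking: Ranking
    replicate_ranks: pd.DataFrame
    rank_frequency: pd.DataFrame = field(init=False)
    median_rank: pd.Series = field(init=False)
    intervals: pd.DataFrame = field(init=False)
    tau: np.ndarray = field(init=False)
    n_undefined_tau: int = field(init=False)
    small_n_caution: bool = False
    interval_level: float = 95.0

    def __post_init__(self) -> None:
        p = self.replicate_ranks.shape[1]
        counts = {
            alg: np.bincount(self.replicate_ranks[alg].astype(int), minlength=p + 1)[1:]
            for alg in self.replicate_ranks.columns
        }
        self.rank_frequency = pd.DataFrame(counts, index=range(1, p + 1)).T
        self.rank_frequency.index.name = "algorithm"
        self.median_rank = self.replicate_ranks.median(axis=0)
        lo, hi = zip(
            *(
                bootstrap_interval(self.replicate_ranks[a].to_numpy(), self.interval_level)
                for a in self.replicate_ranks.columns
            )
        )
        self.intervals = pd.DataFrame(
            {"lower": lo, "upper": hi}, index=self.replicate_ranks.columns
        )
        self.tau = tau_to_full(self.replicate_ranks, self.full_ranking.ranks)
        self.n_undefined_tau = int(np.isnan(self.tau).sum())

    @property
    def algorithms(self) -> list[str]:
        return list(self.replicate_ranks.columns)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "median_rank": self.median_rank,
                "lower": self.intervals["lower"],
                "upper": self.intervals["upper"],
            }
        ).rename_axis("algorithm")

    def to_csv(self, replicates_path, summary_path) -> None:
        """Write replicate-level rankings and the per-algorithm summary."""
        long = (
            self.replicate_ranks.rename_axis("replicate")
            .reset_index()
            .melt(id_vars="replicate", var_name="algorithm", value_name="rank")
            .sort_values(["replicate", "algorithm"], kind="stable")
        )
        long.to_csv(replicates_path, index=False)
        self.summary_frame().to_csv(summary_path)


def bootstrap_rankings(
    slice: TaskSlice,
    method: str | Callable[[TaskSlice], Ranking] = "mean",
    b: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Re-rank b bootstrap resamples of one task.

    ``method`` is a ranking-method name understood by
    :func:`~benchrank.ranking.make_ranker` or a callable
    ``TaskSlice -> Ranking``.  The seed fully determines the resamples;
    identical inputs give a bit-identical result.  Replicates where the
    method ties everything are kept, never dropped.
    """
    if b < 1:
        raise ValueError("b must be at least 1")
    if not slice.is_complete():
        raise ValueError(f"task {slice.task_id!r} has missing values; impute first")
    ranker = make_ranker(method) if isinstance(method, str) else method
    full = ranker(slice)
    n = slice.n_cases
    if n < SMALL_N_CAUTION:
        warnings.warn(
            f"task {slice.task_id!r} has only {n} test cases; bootstrap results "
            "from so few cases should be treated with caution",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    rows = np.empty((b, len(slice.algorithms)), dtype=int)
    for i in range(b):
        resample = slice.resample(rng.integers(0, n, size=n))
        rows[i] = ranker(resample).ranks.reindex(slice.algorithms).to_numpy()
    replicate_ranks = pd.DataFrame(rows, columns=slice.algorithms)
    replicate_ranks.index.name = "replicate"
    return BootstrapResult(
        task_id=slice.task_id,
        method=full.method,
        b=b,
        seed=seed,
        full_ranking=full,
        replicate_ranks=replicate_ranks,
        small_n_caution=n < SMALL_N_CAUTION,
    )


def bootstrap_interval(rank_samples, level: float = 95.0) -> tuple[float, float]:
    """Percentile interval of a bootstrap rank distribution.

    Returns the empirical ((100-level)/2, 100-(100-level)/2)
    percentiles with linear interpolation between order statistics
    (for the default 95% level: the 2.5th and 97.5th percentiles).
    """
    samples = np.asarray(rank_samples, dtype=float)
    if samples.size == 0:
        raise ValueError("rank_samples must be non-empty")
    if not 0.0 < level < 100.0:
        raise ValueError("level must lie strictly between 0 and 100")
    half = (100.0 - level) / 2.0
    lo, hi = np.percentile(samples, [half, 100.0 - half], method="linear")
    return float(lo), float(hi)


def tau_to_full(replicate_ranks: pd.DataFrame, full_ranking) -> np.ndarray:
    """Kendall's tau of each replicate ranking vs the full-data ranking.

    Returns one tau per replicate in replicate order; replicates whose
    ranking is fully tied (tau undefined) yield NaN — these are
    excluded from violin plots and their count is reported.
    """
    full = full_ranking.ranks if isinstance(full_ranking, Ranking) else pd.Series(full_ranking)
    if set(replicate_ranks.columns) != set(full.index):
        raise ValueError("replicate rankings and full ranking cover different algorithms")
    full = full.reindex(replicate_ranks.columns)
    out = np.empty(len(replicate_ranks))
    if replicate_ranks.shape[1] < 2:
        out[:] = np.nan  # tau needs at least two algorithms
        return out
    for i, (_, row) in enumerate(replicate_ranks.iterrows()):
        try:
            out[i] = kendalls_tau(row.to_numpy(), full.to_numpy())
        except UndefinedTauError:
            out[i] = np.nan
    return out
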