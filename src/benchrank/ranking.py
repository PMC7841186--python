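"""The three challenge ranking schemes with the min-rank tie convention.

* ``aggregate_then_rank`` — aggregate metric values across test cases
  (mean, median or another quantile) per algorithm, then rank the
  aggregates.
* ``rank_then_aggregate`` — rank algorithms within each test case
  first, aggregate the per-case ranks per algorithm, then rank the
  aggregated ranks ("rank first").
* ``test_then_rank`` — count, for each algorithm, the number of
  pairwise one-sided Wilcoxon signed-rank tests (Holm-adjusted within
  the task) in which it is significantly superior; rank by that count.

Ties receive the minimum of the ranks they span: if the two best
algorithms tie, both are declared winners with rank 1 and the next
algorithm gets rank 3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from benchrank.data_model import TaskSlice

__all__ = [
    "Ranking",
    "rank_with_ties",
    "aggregate_then_rank",
    "rank_then_aggregate",
    "test_then_rank",
    "make_ranker",
]


@dataclass(frozen=True)
class Ranking:
    """Per-task ranking of algorithms (rank 1 = best, min-rank ties).

    ``aggregates`` holds the per-algorithm summary the ranks were
    derived from (mean/median metric value, mean per-case rank, or
    significant-superiority count); it is NaN-free except where a
    method defines no aggregate.
    """

    task_id: str
    method: str
    ranks: pd.Series  # algorithm -> int rank
    aggregates: pd.Series  # algorithm -> float summary

    @property
    def algorithms(self) -> list[str]:
        return list(self.ranks.index)

    def ordered(self) -> list[str]:
        """Algorithms sorted best-first (ties kept in column order)."""
        return list(self.ranks.sort_values(kind="stable").index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"aggregate": self.aggregates, "rank": self.ranks}).rename_axis(
            "algorithm"
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def rank_with_ties(
    values, small_better: bool = False, tie_rule: str = "min"
) -> np.ndarray:
    """Rank values so that the best value gets rank 1.

    Parameters
    ----------
    values:
        Finite values to rank, one per algorithm.
    small_better:
        If False (default) larger values are better.
    tie_rule:
        ``"min"`` — tied values share the minimum of the spanned ranks
        (integer ranks); ``"average"`` — tied values share the average
        (possibly half-integer), used when building consensus rankings.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot rank an empty value list")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite; impute missing values first")
    if tie_rule not in ("min", "average"):
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    ranks = stats.rankdata(arr if small_better else -arr, method=tie_rule)
    return ranks.astype(int) if tie_rule == "min" else ranks


def _aggregator(agg) -> tuple[str, Callable[[pd.DataFrame], pd.Series]]:
    """Resolve an aggregation spec to (label, column-wise function)."""
    if callable(agg):
        return getattr(agg, "__name__", "custom"), lambda df: df.apply(agg, axis=0)
    if agg == "mean":
        return "mean", lambda df: df.mean(axis=0)
    if agg == "median":
        # mid-point convention for an even number of values
        return "median", lambda df: df.median(axis=0)
    if isinstance(agg, tuple) and len(agg) == 2 and agg[0] == "quantile":
        q = float(agg[1])
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"quantile must lie in [0, 1], got {q}")
        # empirical quantile with linear interpolation between order statistics
        return f"q{q:g}", lambda df: df.quantile(q, axis=0, interpolation="linear")
    raise ValueError(f"unknown aggregation spec {agg!r}")


def aggregate_then_rank(slice: TaskSlice, agg="mean", small_better: bool | None = None) -> Ranking:
    """Aggregate metric values across cases per algorithm, then rank.

    ``agg`` is ``"mean"``, ``"median"``, ``("quantile", q)`` or a
    callable mapping a value vector to a scalar.
    """
    small_better = slice.small_better if small_better is None else small_better
    if not slice.is_complete():
        raise ValueError(f"task {slice.task_id!r} has missing values; impute first")
    label, fn = _aggregator(agg)
    aggregates = fn(slice.values)
    ranks = rank_with_ties(aggregates.to_numpy(), small_better=small_better)
    return Ranking(
        slice.task_id,
        f"aggregate_then_rank({label})",
        pd.Series(ranks, index=aggregates.index),
        aggregates,
    )


def rank_then_aggregate(slice: TaskSlice, agg="mean", small_better: bool | None = None) -> Ranking:
    """Rank within each test case, aggregate per-case ranks, re-rank.

    Per-case ranks use the min-tie rule; the aggregated rank is itself
    ranked with min ties, smaller aggregated rank being better.
    """
    small_better = slice.small_better if small_better is None else small_better
    if not slice.is_complete():
        raise ValueError(f"task {slice.task_id!r} has missing values; impute first")
    per_case = per_case_ranks(slice, small_better=small_better)
    label, fn = _aggregator(agg)
    mean_ranks = fn(per_case)
    final = rank_with_ties(mean_ranks.to_numpy(), small_better=True)
    return Ranking(
        slice.task_id,
        f"rank_then_aggregate({label})",
        pd.Series(final, index=mean_ranks.index),
        mean_ranks,
    )


def per_case_ranks(slice: TaskSlice, small_better: bool | None = None) -> pd.DataFrame:
    """Min-tie ranks of the algorithms within every test case."""
    small_better = slice.small_better if small_better is None else small_better
    out = np.vstack(
        [rank_with_ties(row, small_better=small_better) for row in slice.values.to_numpy()]
    )
    return pd.DataFrame(out, index=slice.values.index, columns=slice.values.columns)


def test_then_rank(
    slice: TaskSlice,
    alpha: float = 0.05,
    small_better: bool | None = None,
    exact_threshold: int = 25,
) -> Ranking:
    """Rank algorithms by their number of significant pairwise wins.

    For every ordered pair (A, B) a one-sided paired Wilcoxon
    signed-rank test of "A superior to B" is computed; Holm adjustment
    is applied over the family of all p(p-1) one-sided tests within the
    task.  Each algorithm's score is its count of significant
    superiorities; algorithms are ranked by descending score with min
    ties, so algorithms with equal counts share a rank.
    """
    from benchrank.significance import significance_matrix

    small_better = slice.small_better if small_better is None else small_better
    if slice.n_cases < 2:
        raise ValueError("test-based ranking needs at least 2 test cases")
    sig = significance_matrix(
        slice, alpha=alpha, small_better=small_better, exact_threshold=exact_threshold
    )
    scores = sig.significant.sum(axis=1).astype(float)
    ranks = rank_with_ties(scores.to_numpy(), small_better=False)
    return Ranking(
        slice.task_id,
        f"test_then_rank(alpha={alpha:g})",
        pd.Series(ranks, index=scores.index),
        scores,
    )


# not a pytest test, despite the name
test_then_rank.__test__ = False  # type: ignore[attr-defined]

#: CLI / config names for the ranking methods
METHOD_NAMES = ("mean", "median", "rank-then-mean", "rank-then-median", "significance")


def make_ranker(method: str, alpha: float = 0.05, q: float | None = None) -> Callable[[TaskSlice], Ranking]:
    """Build a ``TaskSlice -> Ranking`` callable from a method name.

    Recognized names: ``mean``, ``median``, ``quantile`` (requires
    ``q``), ``rank-then-mean``, ``rank-then-median``, ``significance``.
    """
    if method == "mean":
        return lambda s: aggregate_then_rank(s, "mean")
    if method == "median":
        return lambda s: aggregate_then_rank(s, "median")
    if method == "quantile":
        if q is None:
            raise ValueError("method 'quantile' requires q")
        return lambda s: aggregate_then_rank(s, ("quantile", q))
    if method == "rank-then-mean":
        return lambda s: rank_then_aggregate(s, "mean")
    if method == "rank-then-median":
        return lambda s: rank_then_aggregate(s, "median")
    if method == "significance":
        return lambda s: test_then_rank(s, alpha=alpha)
    raise ValueError(f"unknown ranking method {method!r}; choose from {METHOD_NAMES}")
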