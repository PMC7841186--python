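"""Rank-list comparison measures and cross-task consensus rankings.

Two ranking lists over the same algorithms can be compared with
Kendall's tau (correlation from pairwise concordances/discordances, in
[-1, 1]), Spearman's footrule (sum of absolute rank differences, 0 for
complete concordance) or Spearman's distance (sum of squared rank
differences).

A consensus ranking across tasks can be obtained either by averaging
per-task ranks (average-rank tie convention within each task) and
ranking those averages, or by searching for the ordering that minimizes
the summed rank distance to all per-task rankings.  With Spearman's
distance the two coincide: the mean-rank ordering is always among the
distance minimizers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from benchrank.ranking import Ranking, rank_with_ties

__all__ = [
    "UndefinedTauError",
    "kendalls_tau",
    "spearman_footrule",
    "spearman_distance",
    "consensus_rank",
    "ConsensusResult",
]


class UndefinedTauError(ValueError):
    """Raised when Kendall's tau is undefined (a fully tied ranking)."""


def _align(r1, r2) -> tuple[np.ndarray, np.ndarray]:
    """Align two rank vectors on their common algorithm set."""
    if isinstance(r1, Ranking):
        r1 = r1.ranks
    if isinstance(r2, Ranking):
        r2 = r2.ranks
    s1 = pd.Series(r1, dtype=float)
    s2 = pd.Series(r2, dtype=float)
    if isinstance(r1, dict) or isinstance(r1, pd.Series) or isinstance(r2, dict) or isinstance(
        r2, pd.Series
    ):
        if set(s1.index) != set(s2.index):
            raise ValueError(
                "rank vectors cover different algorithm sets: "
                f"{sorted(set(s1.index) ^ set(s2.index))}"
            )
        s2 = s2.reindex(s1.index)
    elif len(s1) != len(s2):
        raise ValueError("rank vectors differ in length")
    return s1.to_numpy(), s2.to_numpy()


def kendalls_tau(r1, r2) -> float:
    """Tie-corrected Kendall's tau (tau-b) between two rank vectors.

    Returns 1 for identical order, -1 for fully inverted order.  Raises
    :class:`UndefinedTauError` when either vector is fully tied, since
    the concordance denominator is then zero.
    """
    a, b = _align(r1, r2)
    if len(a) < 2:
        raise ValueError("need at least 2 algorithms to compare rankings")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise UndefinedTauError("Kendall's tau is undefined for a fully tied ranking")
    tau = stats.kendalltau(a, b, variant="b").statistic
    if np.isnan(tau):
        raise UndefinedTauError("Kendall's tau is undefined for these rankings")
    # shed float noise so exact concordance/inversion report exactly +/-1
    return float(np.clip(round(tau, 12), -1.0, 1.0))


def spearman_footrule(r1, r2) -> float:
    """Sum of absolute rank differences; 0 for complete concordance."""
    a, b = _align(r1, r2)
    return float(np.abs(a - b).sum())


def spearman_distance(r1, r2) -> float:
    """Sum of squared rank differences; 0 for complete concordance."""
    a, b = _align(r1, r2)
    return float(((a - b) ** 2).sum())


_DISTANCES = {"footrule": spearman_footrule, "spearman": spearman_distance}


@dataclass(frozen=True)
class ConsensusResult:
    """Cross-task consensus ranking and its inputs.

    ``rank_matrix`` is tasks x algorithms with the average-rank tie
    convention applied inside each task; ``mean_rank`` averages each
    algorithm's ranks across tasks (each task weighted equally,
    independent of its sample size or stability); ``consensus`` ranks
    those averages with min ties.
    """

    rank_matrix: pd.DataFrame
    mean_rank: pd.Series
    consensus: pd.Series
    method: str

    @property
    def algorithms(self) -> list[str]:
        return list(self.consensus.index)

    def ordered(self) -> list[str]:
        return list(self.consensus.sort_values(kind="stable").index)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"mean_rank": self.mean_rank, "consensus_rank": self.consensus}
        )
        for task in self.rank_matrix.index:
            out[f"rank_{task}"] = self.rank_matrix.loc[task]
        return out.rename_axis("algorithm")

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def _as_rank_matrix(per_task_rankings) -> pd.DataFrame:
    """Normalize input rankings into a tasks x algorithms rank matrix
    with the average-tie convention inside each task."""
    rows = {}
    if isinstance(per_task_rankings, pd.DataFrame):
        items = [(t, per_task_rankings.loc[t]) for t in per_task_rankings.index]
    elif isinstance(per_task_rankings, dict):
        items = list(per_task_rankings.items())
    else:
        items = []
        for i, r in enumerate(per_task_rankings):
            items.append((r.task_id if isinstance(r, Ranking) else f"T{i + 1}", r))
    for task, r in items:
        ranks = r.ranks if isinstance(r, Ranking) else pd.Series(r, dtype=float)
        # re-express min-tie (or any) ranks in the average-tie convention
        rows[task] = pd.Series(
            rank_with_ties(ranks.to_numpy(), small_better=True, tie_rule="average"),
            index=ranks.index,
        )
    mat = pd.DataFrame(rows).T
    if mat.isna().any().any():
        bad = sorted(mat.columns[mat.isna().any()])
        raise ValueError(f"algorithm sets differ across tasks; asymmetric algorithms: {bad}")
    return mat


def _distance_minimizing_order(mat: pd.DataFrame, distance: str) -> list[str]:
    """Ordering minimizing the summed distance to all per-task rankings.

    Exhaustive over all p! candidate orderings for p <= 8, local
    pairwise-swap search from the mean-rank ordering otherwise.  Among
    tied minimizers the lexicographically smallest algorithm ordering
    is returned.
    """
    dist = _DISTANCES[distance]
    algs = list(mat.columns)
    task_ranks = mat.to_numpy()

    def objective(order: tuple[str, ...]) -> float:
        cand = np.empty(len(algs))
        for pos, a in enumerate(order):
            cand[algs.index(a)] = pos + 1
        return sum(dist(cand, row) for row in task_ranks)

    if len(algs) <= 8:
        best, best_obj = None, np.inf
        for perm in itertools.permutations(sorted(algs)):
            obj = objective(perm)
            if obj < best_obj - 1e-12:
                best, best_obj = perm, obj
        return list(best)

    order = list(mat.mean(axis=0).sort_values(kind="stable").index)
    improved = True
    while improved:
        improved = False
        cur = objective(tuple(order))
        for i in range(len(order)):
            for j in range(i + 1, len(order)):
                trial = order.copy()
                trial[i], trial[j] = trial[j], trial[i]
                if objective(tuple(trial)) < cur - 1e-12:
                    order, cur, improved = trial, objective(tuple(trial)), True
    return order


def consensus_rank(per_task_rankings, method: str = "mean") -> ConsensusResult:
    """Aggregate per-task rankings into a cross-task consensus.

    Parameters
    ----------
    per_task_rankings:
        Mapping/list of :class:`~benchrank.ranking.Ranking` objects or
        rank vectors (Series/dict algorithm -> rank), or a tasks x
        algorithms DataFrame.  All tasks must cover the same algorithms.
    method:
        ``"mean"`` — average the per-task ranks (average-tie convention
        within each task) and rank the averages with min ties.
        ``"footrule"`` / ``"spearman"`` — ordering that minimizes the
        summed footrule / squared-rank distance to the per-task
        rankings (exhaustive for p <= 8, mean-rank-seeded swap search
        beyond).
    """
    mat = _as_rank_matrix(per_task_rankings)
    mean_rank = mat.mean(axis=0)

    if method == "mean":
        consensus = pd.Series(
            rank_with_ties(mean_rank.to_numpy(), small_better=True), index=mat.columns
        )
    elif method in _DISTANCES:
        order = _distance_minimizing_order(mat, method)
        consensus = pd.Series(
            {a: pos + 1 for pos, a in enumerate(order)}, index=mat.columns
        ).astype(int)
    else:
        raise ValueError(f"unknown consensus method {method!r}")
    return ConsensusResult(mat, mean_rank, consensus, method)
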