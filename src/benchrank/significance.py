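"""Pairwise one-sided Wilcoxon signed-rank testing with Holm adjustment.

The testing route to ranking stability asks, for every ordered pair of
algorithms (A, B), whether A's per-case metric values are significantly
superior to B's.  The paired one-sided Wilcoxon signed-rank test is
used because it compares exactly the two algorithms at hand — its
outcome does not change when other algorithms are added to or dropped
from the challenge.  Family-wise error over the p(p-1) ordered pairs of
one task is controlled with Holm's step-down procedure.

The exact null distribution of the signed-rank statistic is computed by
convolution over the (mid-)ranks of the nonzero paired differences,
which is equivalent to full enumeration of the 2^n sign assignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from benchrank.data_model import TaskSlice

__all__ = [
    "WilcoxonResult",
    "SignificanceMatrix",
    "wilcoxon_one_sided",
    "holm_adjust",
    "significance_matrix",
]


@dataclass(frozen=True)
class WilcoxonResult:
    """Outcome of one one-sided paired Wilcoxon signed-rank test.

    ``degenerate`` is True when all paired differences are zero, in
    which case ``pvalue`` is 1 (no evidence either way).  ``n_zeros``
    counts the zero differences dropped before ranking magnitudes.
    """

    pvalue: float
    statistic: float
    n_used: int
    n_zeros: int
    method: str  # "exact" | "normal" | "degenerate"

    @property
    def degenerate(self) -> bool:
        return self.method == "degenerate"

    def __float__(self) -> float:
        return self.pvalue


def _exact_sf(ranks: np.ndarray, w_obs: float) -> float:
    """P(W+ >= w_obs) under random signs, by convolution over ranks.

    Ranks may be midranks (half-integers); doubling makes them integer.
    The distribution of W+ = sum of ranks with positive sign over all
    2^n equiprobable sign assignments is built by convolving one
    two-point distribution per rank — identical to full enumeration.
    """
    doubled = np.rint(2 * ranks).astype(np.int64)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    threshold = int(np.ceil(2 * w_obs - 1e-9))  # W+ is a multiple of 1/2, so 2*W+ is integral
    return float(counts[threshold:].sum() / counts.sum())


def wilcoxon_one_sided(
    x,
    y,
    small_better: bool = False,
    exact_threshold: int = 25,
) -> WilcoxonResult:
    """One-sided paired Wilcoxon signed-rank test of "x superior to y".

    Superiority follows the metric direction: with larger-is-better
    metrics the alternative is that x's values tend to exceed y's.
    Zero differences are dropped before ranking the magnitudes (the
    classic convention); their count is reported.  The exact
    sign-assignment distribution is used for up to ``exact_threshold``
    nonzero pairs, a normal approximation with continuity and tie
    correction beyond that.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 paired values")
    d = y - x if small_better else x - y
    nonzero = d != 0
    n_zeros = int((~nonzero).sum())
    d = d[nonzero]
    n = len(d)
    if n == 0:
        return WilcoxonResult(1.0, 0.0, 0, n_zeros, "degenerate")

    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_threshold:
        p = _exact_sf(ranks, w_plus)
        return WilcoxonResult(min(p, 1.0), w_plus, n, n_zeros, "exact")

    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    z = (w_plus - mean - 0.5) / np.sqrt(var)
    p = float(stats.norm.sf(z))
    return WilcoxonResult(min(p, 1.0), w_plus, n, n_zeros, "normal")


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order.

    Equivalent to sorting ascending, multiplying the i-th smallest by
    (m - i + 1), enforcing monotonicity by running maximum and capping
    at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


@dataclass(frozen=True)
class SignificanceMatrix:
    """Adjusted p-values and incidence of pairwise one-sided superiority.

    ``p_adjusted[(A, B)]`` (row A, column B) is the Holm-adjusted
    p-value for "A superior to B"; the diagonal is NaN.  ``significant``
    is the boolean incidence at level ``alpha``.
    """

    p_adjusted: pd.DataFrame
    significant: pd.DataFrame
    alpha: float
    n_degenerate: int = 0

    @property
    def algorithms(self) -> list[str]:
        return list(self.p_adjusted.index)

    def to_csv(self, path) -> None:
        self.p_adjusted.rename_axis("algorithm").to_csv(path)


def significance_matrix(
    slice: TaskSlice,
    alpha: float = 0.05,
    small_better: bool | None = None,
    exact_threshold: int = 25,
) -> SignificanceMatrix:
    """All-pairs one-sided superiority tests for one task.

    Computes the p(p-1) one-sided Wilcoxon signed-rank tests, applies
    Holm over that whole within-task family, and thresholds at
    ``alpha``.
    """
    small_better = slice.small_better if small_better is None else small_better
    if not slice.is_complete():
        raise ValueError(f"task {slice.task_id!r} has missing values; impute first")
    if slice.n_cases < 2:
        raise ValueError("significance testing needs at least 2 test cases")
    algs = slice.algorithms
    vals = slice.values
    pairs: list[tuple[str, str]] = [(a, b) for a in algs for b in algs if a != b]
    raw = np.empty(len(pairs))
    n_degenerate = 0
    for i, (a, b) in enumerate(pairs):
        res = wilcoxon_one_sided(
            vals[a].to_numpy(),
            vals[b].to_numpy(),
            small_better=small_better,
            exact_threshold=exact_threshold,
        )
        raw[i] = res.pvalue
        n_degenerate += res.degenerate

    adj = holm_adjust(raw)
    p_adjusted = pd.DataFrame(np.nan, index=algs, columns=algs)
    for (a, b), p in zip(pairs, adj):
        p_adjusted.loc[a, b] = p
    significant = (p_adjusted <= alpha).fillna(False).astype(bool)
    return SignificanceMatrix(p_adjusted, significant, alpha, n_degenerate)
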