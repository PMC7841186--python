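"""The three ranking schemes and the min-rank tie convention."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from benchrank.ranking import (
    aggregate_then_rank,
    rank_then_aggregate,
    rank_with_ties,
    test_then_rank,
    make_ranker,
)

from conftest import make_slice


def assert_min_tie_layout(ranks):
    """Tied algorithms share the minimum spanned rank; after a tie of k
    algorithms at rank r, the next distinct rank is r + k."""
    ranks = sorted(ranks)
    expected = 1
    i = 0
    while i < len(ranks):
        k = ranks.count(ranks[i])
        assert ranks[i] == expected
        expected += k
        i += k


class TestRankWithTies:
    @pytest.mark.parametrize(
        "values, small_better, tie_rule, expected",
        [
            ([0.9, 0.7, 0.9], False, "min", [1, 3, 1]),
            ([0.5, 0.5, 0.5], False, "min", [1, 1, 1]),
            ([0.9, 0.7, 0.9], False, "average", [1.5, 3, 1.5]),
            ([0.1, 0.3, 0.2], True, "min", [1, 3, 2]),
            ([4.0], False, "min", [1]),
        ],
    )
    def test_examples(self, values, small_better, tie_rule, expected):
        assert rank_with_ties(values, small_better, tie_rule).tolist() == expected

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="finite"):
            rank_with_ties([0.5, np.nan])

    @given(st.lists(st.integers(0, 5), min_size=1, max_size=12))
    def test_min_tie_layout_always_holds(self, values):
        assert_min_tie_layout(rank_with_ties(values).tolist())


class TestAggregateThenRank:
    def test_separated_means(self):
        sl = make_slice({"A": [0.9, 0.8], "B": [0.7, 0.6]})
        r = aggregate_then_rank(sl, "mean")
        assert r.ranks.to_dict() == {"A": 1, "B": 2}
        assert r.aggregates.to_dict() == {"A": pytest.approx(0.85), "B": pytest.approx(0.65)}

    def test_ideal_strata_force_index_order(self, ideal_slice):
        r = aggregate_then_rank(ideal_slice, "mean")
        assert r.ranks.to_dict() == {f"A{k}": k for k in range(1, 6)}

    def test_median_midpoint_tie(self):
        sl = make_slice({"A": [1.0, 0.0], "B": [0.6, 0.4]})
        r = aggregate_then_rank(sl, "median")
        assert r.aggregates.to_dict() == {"A": 0.5, "B": 0.5}
        assert r.ranks.to_dict() == {"A": 1, "B": 1}

    def test_quantile_aggregation(self):
        sl = make_slice({"A": [0.0, 1.0, 2.0], "B": [0.5, 0.5, 0.5]})
        r = aggregate_then_rank(sl, ("quantile", 0.25))
        # linear-interpolation 25th percentiles: A -> 0.5, B -> 0.5
        assert r.ranks.to_dict() == {"A": 1, "B": 1}


class TestRankThenAggregate:
    def test_consistent_winner(self):
        sl = make_slice({"A": [0.9, 0.8], "B": [0.7, 0.6]})
        r = rank_then_aggregate(sl, "mean")
        assert r.ranks.to_dict() == {"A": 1, "B": 2}

    def test_split_decisions_tie(self):
        sl = make_slice({"A": [0.9, 0.4], "B": [0.7, 0.6]})
        r = rank_then_aggregate(sl, "mean")
        assert r.aggregates.to_dict() == {"A": 1.5, "B": 1.5}
        assert r.ranks.to_dict() == {"A": 1, "B": 1}

    def test_total_separation_matches_aggregate_first(self, ideal_slice):
        a = aggregate_then_rank(ideal_slice, "mean")
        b = rank_then_aggregate(ideal_slice, "mean")
        assert a.ranks.to_dict() == b.ranks.to_dict() == {f"A{k}": k for k in range(1, 6)}


class TestTestThenRank:
    def test_complete_separation_scores_descend(self):
        sl = make_slice(
            {
                "A": [0.9 + 0.001 * i for i in range(10)],
                "B": [0.7 + 0.001 * i for i in range(10)],
                "C": [0.5 + 0.001 * i for i in range(10)],
            }
        )
        # smallest exact one-sided p is 2^-10, surviving Holm over 6 tests
        r = test_then_rank(sl, alpha=0.05)
        assert r.aggregates.to_dict() == {"A": 2.0, "B": 1.0, "C": 0.0}
        assert r.ranks.to_dict() == {"A": 1, "B": 2, "C": 3}

    def test_identical_algorithms_all_rank_one(self):
        sl = make_slice({"A": [0.5, 0.6, 0.7], "B": [0.5, 0.6, 0.7], "C": [0.5, 0.6, 0.7]})
        r = test_then_rank(sl)
        assert r.ranks.to_dict() == {"A": 1, "B": 1, "C": 1}

    def test_three_cases_cannot_reach_significance(self):
        # exact one-sided p for 3 consistent wins is 1/8 > 0.05
        sl = make_slice({"A": [0.9, 0.8, 0.7], "B": [0.5, 0.4, 0.3]})
        r = test_then_rank(sl, alpha=0.05)
        assert r.ranks.to_dict() == {"A": 1, "B": 1}

    def test_single_case_rejected(self):
        sl = make_slice({"A": [0.9], "B": [0.7]})
        with pytest.raises(ValueError, match="2 test cases"):
            test_then_rank(sl)


def test_all_methods_agree_on_separated_data(ideal_slice):
    expected = {f"A{k}": k for k in range(1, 6)}
    for name in ("mean", "median", "rank-then-mean", "rank-then-median", "significance"):
        assert make_ranker(name)(ideal_slice).ranks.to_dict() == expected


@given(st.permutations(list(range(4))))
def test_relabeling_equivariance(perm):
    """Permuting algorithm labels permutes the ranking identically."""
    values = {"A": [0.9, 0.3], "B": [0.7, 0.6], "C": [0.7, 0.6], "D": [0.1, 0.2]}
    names = list(values)
    sl = make_slice(values)
    base = aggregate_then_rank(sl, "mean").ranks
    shuffled = make_slice({names[p]: values[names[i]] for i, p in enumerate(perm)})
    permuted = aggregate_then_rank(shuffled, "mean").ranks
    for i, p in enumerate(perm):
        assert permuted[names[p]] == base[names[i]]


@given(
    st.lists(
        st.lists(st.integers(0, 3), min_size=3, max_size=3), min_size=2, max_size=6
    )
)
def test_every_method_emits_min_tie_layout(case_rows):
    values = np.asarray(case_rows, dtype=float)
    sl = make_slice({f"A{j}": values[:, j].tolist() for j in range(3)})
    for name in ("mean", "median", "rank-then-mean", "significance"):
        ranks = make_ranker(name)(sl).ranks
        assert_min_tie_layout(list(ranks))
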