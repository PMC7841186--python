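"""Rank-list comparison measures and cross-task consensus rankings."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from benchrank.rank_similarity import (
    UndefinedTauError,
    consensus_rank,
    kendalls_tau,
    spearman_distance,
    spearman_footrule,
)


def tau_by_pair_counting(a, b):
    """Independent oracle: count concordant/discordant pairs directly."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    conc = disc = 0
    for i, j in itertools.combinations(range(len(a)), 2):
        s = np.sign(a[i] - a[j]) * np.sign(b[i] - b[j])
        conc += s > 0
        disc += s < 0
    n0 = len(a) * (len(a) - 1) / 2
    t1 = sum(t * (t - 1) / 2 for t in np.unique(a, return_counts=True)[1])
    t2 = sum(t * (t - 1) / 2 for t in np.unique(b, return_counts=True)[1])
    return (conc - disc) / np.sqrt((n0 - t1) * (n0 - t2))


class TestKendallsTau:
    @pytest.mark.parametrize(
        "r1, r2, expected",
        [
            ([1, 2, 3, 4, 5], [1, 2, 3, 4, 5], 1.0),
            ([1, 2, 3, 4, 5], [5, 4, 3, 2, 1], -1.0),
            ([1, 2, 3], [1, 3, 2], 1 / 3),
        ],
    )
    def test_printed_identities(self, r1, r2, expected):
        assert kendalls_tau(r1, r2) == pytest.approx(expected)

    def test_fully_tied_ranking_is_undefined(self):
        with pytest.raises(UndefinedTauError):
            kendalls_tau([1, 1, 1], [1, 2, 3])

    def test_mismatched_algorithm_sets_rejected(self):
        with pytest.raises(ValueError, match="different algorithm sets"):
            kendalls_tau({"A": 1, "B": 2}, {"A": 1, "C": 2})

    @given(st.lists(st.integers(1, 4), min_size=3, max_size=8))
    def test_matches_pair_counting_oracle_and_symmetry(self, ranks):
        other = list(range(1, len(ranks) + 1))
        if len(set(ranks)) == 1:
            return
        t = kendalls_tau(ranks, other)
        assert t == pytest.approx(tau_by_pair_counting(ranks, other))
        assert t == pytest.approx(kendalls_tau(other, ranks))


class TestRankDistances:
    @pytest.mark.parametrize(
        "fn, r1, r2, expected",
        [
            (spearman_footrule, [1, 2, 3], [1, 2, 3], 0.0),
            (spearman_footrule, [1, 2], [2, 1], 2.0),
            (spearman_footrule, [1, 2, 3], [3, 2, 1], 4.0),
            (spearman_distance, [1, 2, 3], [1, 2, 3], 0.0),
            (spearman_distance, [1, 2], [2, 1], 2.0),
            (spearman_distance, [1, 2, 3], [3, 2, 1], 8.0),
        ],
    )
    def test_examples(self, fn, r1, r2, expected):
        assert fn(r1, r2) == expected

    @given(st.permutations([1, 2, 3, 4]), st.permutations([1, 2, 3, 4]), st.permutations([1, 2, 3, 4]))
    def test_footrule_distance_axioms(self, a, b, c):
        assert spearman_footrule(a, b) == spearman_footrule(b, a)
        assert (spearman_footrule(a, b) == 0) == (list(a) == list(b))
        assert spearman_footrule(a, c) <= spearman_footrule(a, b) + spearman_footrule(b, c)


class TestConsensus:
    def test_mean_rank_consensus_with_ties(self):
        res = consensus_rank({"T1": {"A": 1, "B": 2, "C": 3}, "T2": {"A": 1, "B": 3, "C": 2}})
        assert res.mean_rank.to_dict() == {"A": 1.0, "B": 2.5, "C": 2.5}
        assert res.consensus.to_dict() == {"A": 1, "B": 2, "C": 2}

    def test_single_task_identity(self):
        res = consensus_rank({"T1": {"A": 2, "B": 1, "C": 3}})
        assert res.consensus.to_dict() == {"A": 2, "B": 1, "C": 3}

    def test_min_tie_ranks_converted_to_average_inside_tasks(self):
        # min-tie input (1, 1, 3) is re-expressed as (1.5, 1.5, 3)
        res = consensus_rank({"T1": {"A": 1, "B": 1, "C": 3}})
        assert res.rank_matrix.loc["T1"].to_dict() == {"A": 1.5, "B": 1.5, "C": 3.0}

    def test_spearman_minimizer_ties_resolve_lexicographically(self):
        res = consensus_rank(
            {"T1": {"A": 1, "B": 2, "C": 3}, "T2": {"A": 1, "B": 3, "C": 2}},
            method="spearman",
        )
        # (A,B,C) and (A,C,B) tie at total distance 2; lexicographic pick
        assert res.ordered() == ["A", "B", "C"]

    def test_asymmetric_algorithm_sets_rejected(self):
        with pytest.raises(ValueError, match="asymmetric.*B"):
            consensus_rank({"T1": {"A": 1, "B": 2}, "T2": {"A": 1, "C": 2}})

    def test_each_task_contributes_equally(self):
        # duplicating a task shifts the mean toward it
        base = consensus_rank({"T1": {"A": 1, "B": 2}, "T2": {"A": 2, "B": 1}})
        assert base.mean_rank.to_dict() == {"A": 1.5, "B": 1.5}

    def test_mean_rank_bounds(self):
        res = consensus_rank({"T1": {"A": 1, "B": 2, "C": 3}, "T2": {"A": 3, "B": 2, "C": 1}})
        assert ((res.mean_rank >= 1) & (res.mean_rank <= 3)).all()


def brute_force_spearman_minimum(profiles):
    """Oracle: minimum summed Spearman distance over all tie-free orderings."""
    p = len(profiles[0])
    best = np.inf
    for perm in itertools.permutations(range(1, p + 1)):
        obj = sum(spearman_distance(list(perm), prof) for prof in profiles)
        best = min(best, obj)
    return best


@given(st.lists(st.permutations([1, 2, 3, 4, 5]), min_size=3, max_size=3))
def test_mean_rank_consensus_minimizes_spearman_distance(profiles):
    """The mean-rank ordering is always among the Spearman-distance minimizers."""
    profiles = [list(p) for p in profiles]
    res = consensus_rank({f"T{i}": {f"A{j+1}": r for j, r in enumerate(p)} for i, p in enumerate(profiles)})
    order = res.ordered()
    cand = {a: pos + 1 for pos, a in enumerate(order)}
    obj = sum(
        spearman_distance(
            [cand[f"A{j+1}"] for j in range(5)], prof
        )
        for prof in profiles
    )
    assert obj == pytest.approx(brute_force_spearman_minimum(profiles))
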