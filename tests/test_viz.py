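"""Computed figure data and rendering smoke tests."""

import numpy as np
import pytest

from benchrank import viz
from benchrank.ranking import make_ranker
from benchrank.significance import significance_matrix
from benchrank.stability import bootstrap_rankings

from conftest import make_slice


class TestPodiumData:
    def test_top_stratum_always_first(self, ideal_slice):
        pod = viz.podium_data(ideal_slice, seed=0)
        assert pod.frequencies.loc["A1", 1] == 1.0
        assert (pod.placements[1] == "A1").all()

    def test_each_case_is_a_permutation(self):
        sl = make_slice({"A": [0.5], "B": [0.5]})
        pod = viz.podium_data(sl, seed=3)
        assert sorted(pod.placements.loc["c1"]) == ["A", "B"]

    def test_place_frequencies(self):
        a = [0.9] * 30 + [0.1] * 10
        b = [0.5] * 40
        pod = viz.podium_data(make_slice({"A": a, "B": b}), seed=0)
        assert pod.frequencies.loc["A", 1] == 0.75
        assert pod.frequencies.sum(axis=1).tolist() == pytest.approx([1.0, 1.0])

    def test_tie_break_reproducible_under_seed(self):
        sl = make_slice({"A": [0.5] * 6, "B": [0.5] * 6, "C": [0.5] * 6})
        p1 = viz.podium_data(sl, seed=8)
        p2 = viz.podium_data(sl, seed=8)
        assert p1.placements.equals(p2.placements)


class TestHeatmapCounts:
    def test_ideal_data_is_diagonal(self, ideal_slice):
        hm = viz.heatmap_counts(ideal_slice)
        expected = np.diag([50] * 5)
        np.testing.assert_array_equal(hm.to_numpy(), expected)

    def test_single_case_single_cell_per_column(self):
        hm = viz.heatmap_counts(make_slice({"A": [0.9], "B": [0.7], "C": [0.5]}))
        assert (hm.sum(axis=0) == 1).all()
        assert ((hm != 0).sum(axis=0) == 1).all()

    def test_full_tie_tallies_at_shared_min_rank(self):
        hm = viz.heatmap_counts(make_slice({"A": [0.5] * 10, "B": [0.5] * 10}))
        assert hm.loc[1].tolist() == [10, 10]
        assert hm.loc[2].tolist() == [0, 0]

    def test_column_sums_equal_case_count(self, random_slice):
        hm = viz.heatmap_counts(random_slice)
        assert (hm.sum(axis=0) == random_slice.n_cases).all()


class TestLinePlotData:
    def test_ideal_data_gives_parallel_lines(self, ideal_slice):
        methods = {m: make_ranker(m) for m in ("mean", "median", "rank-then-mean")}
        table = viz.line_plot_data(ideal_slice, methods)
        assert (table.nunique(axis=1) == 1).all()

    def test_outlier_makes_mean_and_median_cross(self):
        # one catastrophic failure drags A's mean below B but not its median
        sl = make_slice({"A": [0.9, 0.9, 0.0], "B": [0.7, 0.7, 0.7]})
        table = viz.line_plot_data(sl, {"mean": make_ranker("mean"), "median": make_ranker("median")})
        assert table.loc["A", "mean"] == 2 and table.loc["A", "median"] == 1
        assert table.loc["B", "mean"] == 1 and table.loc["B", "median"] == 2

    def test_no_methods_rejected(self, ideal_slice):
        with pytest.raises(ValueError):
            viz.line_plot_data(ideal_slice, {})


class TestBlobData:
    def test_constant_group(self):
        out = viz.blob_data({"A": [1, 1, 1]})
        assert out["A"]["frequencies"].to_dict() == {1.0: 3}
        assert out["A"]["interval"] == (1.0, 1.0)

    def test_two_equal_blobs(self):
        out = viz.blob_data({"A": [1, 1, 2, 2]})
        assert out["A"]["frequencies"].to_dict() == {1.0: 2, 2.0: 2}
        assert out["A"]["median"] == 1.5

    def test_frequencies_sum_to_group_size(self, random_slice):
        res = bootstrap_rankings(random_slice, "mean", b=60, seed=2)
        out = viz.blob_data({a: res.replicate_ranks[a] for a in res.algorithms})
        for a in res.algorithms:
            assert out[a]["frequencies"].sum() == 60 == out[a]["size"]


class TestTaskStructure:
    def test_identical_rankings_merge_at_zero(self):
        ranks = {"T1": {"A": 1, "B": 2, "C": 3}, "T2": {"A": 1, "B": 2, "C": 3}}
        linkage, labels = viz.dendrogram_data(ranks)
        assert labels == ["T1", "T2"]
        assert linkage[0, 2] == 0.0

    def test_inverted_task_merges_at_footrule_four(self):
        ranks = {
            "T1": {"A": 1, "B": 2, "C": 3},
            "T2": {"A": 1, "B": 2, "C": 3},
            "T3": {"A": 3, "B": 2, "C": 1},
        }
        linkage, _ = viz.dendrogram_data(ranks, distance="footrule")
        heights = sorted(linkage[:, 2])
        assert heights == [0.0, 4.0]

    def test_network_edge_lengths(self):
        ranks = {"T1": {"A": 1, "B": 2, "C": 3}, "T2": {"A": 3, "B": 2, "C": 1}}
        g = viz.network_data(ranks, growth_rate=0.05)
        edge = g.edges["T1", "T2"]
        assert edge["distance"] == 4.0
        assert edge["length"] == pytest.approx(np.exp(0.2))
        same = viz.network_data({"T1": {"A": 1, "B": 2}, "T2": {"A": 1, "B": 2}})
        assert same.edges["T1", "T2"]["length"] == pytest.approx(1.0)

    def test_tied_winner_leaves_node_uncolored(self):
        g = viz.network_data({"T1": {"A": 1, "B": 1, "C": 3}, "T2": {"A": 1, "B": 2, "C": 3}})
        assert g.nodes["T1"]["winner"] is None
        assert g.nodes["T2"]["winner"] == "A"


class TestRender:
    def test_all_kinds_produce_nonempty_files(self, tmp_path, ideal_slice):
        boot = bootstrap_rankings(ideal_slice, "mean", b=30, seed=1)
        ranks = {
            "T1": {"A": 1, "B": 2, "C": 3},
            "T2": {"A": 2, "B": 1, "C": 3},
            "T3": {"A": 3, "B": 2, "C": 1},
        }
        payload = {
            "dot_box": ideal_slice,
            "podium": viz.podium_data(ideal_slice, seed=0),
            "heatmap": viz.heatmap_counts(ideal_slice),
            "line": viz.line_plot_data(ideal_slice, {"mean": make_ranker("mean")}),
            "blob": viz.blob_data({a: boot.replicate_ranks[a] for a in boot.algorithms}),
            "violin": boot.tau,
            "significance_map": significance_matrix(ideal_slice),
            "dendrogram": viz.dendrogram_data(ranks),
            "network": viz.network_data(ranks),
        }
        for kind, data in payload.items():
            out = tmp_path / f"{kind}.png"
            viz.render(kind, data, out)
            assert out.stat().st_size > 0

    def test_unknown_kind_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown figure kind"):
            viz.render("piechart", None, tmp_path / "x.png")

    def test_podium_refuses_too_many_algorithms(self, tmp_path, rng):
        sl = make_slice({f"A{i}": rng.random(3).tolist() for i in range(31)})
        pod = viz.podium_data(sl, seed=0)
        with pytest.raises(ValueError, match="top list"):
            viz.render("podium", pod, tmp_path / "pod.png")
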