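"""Challenge-analysis figures: computed plot data and rendering.

Every figure type is split into a pure computation (testable without a
display: podium placements, rank-frequency counts, blob summaries,
cluster trees, graph layouts) and a `render` step that turns the
computed data into an image file.  Re-running any computation with the
same inputs and seed is bit-identical.

Figure family
-------------
dot_box           jittered per-case dots over boxplots of metric values
podium            per-case podium placements with spaghetti lines and
                  place-frequency bars
heatmap           per-case ("rank first") rank frequencies per algorithm
line              ranks under several ranking methods, one line per
                  algorithm (parallel lines = robust ranking)
blob              rank distributions (bootstrap replicates, tasks, or
                  task x bootstrap) as area-scaled blobs with median and
                  95% interval
violin            distribution of Kendall's tau between full-data and
                  bootstrap rankings
significance_map  incidence of pairwise significant one-sided
                  superiority (yellow above / blue below)
dendrogram        complete-linkage clustering of tasks by ranking
                  distance
network           tasks as nodes, edge lengths growing exponentially in
                  ranking distance, nodes colored by unique task winner
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import networkx as nx
import seaborn as sns
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from benchrank.data_model import TaskSlice
from benchrank.ranking import Ranking, per_case_ranks
from benchrank.rank_similarity import _as_rank_matrix, spearman_footrule, spearman_distance
from benchrank.significance import SignificanceMatrix
from benchrank.stability import BootstrapResult, bootstrap_interval

__all__ = [
    "PodiumData",
    "podium_data",
    "heatmap_counts",
    "line_plot_data",
    "blob_data",
    "dendrogram_data",
    "network_data",
    "render",
    "FIGURE_KINDS",
]

#: above this many algorithms the podium plot refuses to render
PODIUM_ALGORITHM_LIMIT = 30


# ---------------------------------------------------------------------------
# computed data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PodiumData:
    """Per-case podium placements and per-algorithm place frequencies.

    ``placements.loc[case, place]`` names the algorithm standing on
    podium place ``place`` (1 = best) for that test case; each row is a
    permutation of the algorithms, ties broken randomly under the
    generating seed.  ``frequencies.loc[alg, place]`` is the relative
    frequency with which ``alg`` achieved that place; rows sum to 1.
    """

    placements: pd.DataFrame
    values: pd.DataFrame
    frequencies: pd.DataFrame
    seed: int

    @property
    def algorithms(self) -> list[str]:
        return list(self.values.columns)


def podium_data(slice: TaskSlice, small_better: bool | None = None, seed: int = 0) -> PodiumData:
    """Assign every test case's algorithms to podium places 1..p.

    The place of an algorithm on a case is its rank on that case; tied
    algorithms are assigned the spanned places in random order under
    ``seed`` (logged in the result so plots are reproducible).
    """
    small_better = slice.small_better if small_better is None else small_better
    if not slice.is_complete():
        raise ValueError(f"task {slice.task_id!r} has missing values; impute first")
    rng = np.random.default_rng(seed)
    algs = np.asarray(slice.algorithms)
    p = len(algs)
    vals = slice.values.to_numpy()
    placements = []
    for row in vals:
        noise = rng.random(p)  # random tie-break within equal values
        order = np.lexsort((noise, row if small_better else -row))
        placed = np.empty(p, dtype=object)
        placed[:] = algs[order]
        placements.append(placed)
    placements = pd.DataFrame(placements, index=slice.values.index, columns=range(1, p + 1))
    placements.columns.name = "place"
    freq = pd.DataFrame(0.0, index=algs, columns=range(1, p + 1))
    for place in placements.columns:
        counts = placements[place].value_counts()
        freq.loc[counts.index, place] = counts / len(placements)
    freq.index.name = "algorithm"
    return PodiumData(placements, slice.values, freq, seed)


def heatmap_counts(slice: TaskSlice, small_better: bool | None = None) -> pd.DataFrame:
    """Ranks x algorithms matrix of per-case rank frequencies.

    Cell (i, A) counts the test cases in which algorithm A achieved
    per-case rank i under the min-tie rule (tied cases all tally at the
    shared minimum rank).  Every column sums to the case count.
    """
    ranks = per_case_ranks(slice, small_better=small_better)
    p = ranks.shape[1]
    out = pd.DataFrame(
        {alg: np.bincount(ranks[alg].astype(int), minlength=p + 1)[1:] for alg in ranks.columns},
        index=range(1, p + 1),
    )
    out.index.name = "rank"
    return out


def line_plot_data(slice: TaskSlice, methods) -> pd.DataFrame:
    """Ranks of every algorithm under each ranking method.

    ``methods`` maps method labels to ``TaskSlice -> Ranking``
    callables.  Columns with identical values across all methods show
    as parallel (horizontal) lines, i.e. a ranking robust to the choice
    of method.
    """
    if not methods:
        raise ValueError("need at least one ranking method")
    table = {}
    for name, ranker in methods.items():
        table[name] = ranker(slice).ranks
    return pd.DataFrame(table).rename_axis("algorithm")


def blob_data(rank_samples: dict, level: float = 95.0) -> dict:
    """Summaries behind a blob plot, for an arbitrary grouping.

    ``rank_samples`` maps each group (an algorithm for bootstrap blobs,
    a task for cross-task blobs, ...) to its observed ranks.  Each
    group gets its rank-frequency table (counts summing to the group
    size), median rank and percentile interval.
    """
    if not rank_samples:
        raise ValueError("need at least one group")
    out = {}
    for group, ranks in rank_samples.items():
        arr = np.asarray(list(ranks), dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {group!r} is empty")
        values, counts = np.unique(arr, return_counts=True)
        out[group] = {
            "frequencies": pd.Series(counts, index=values),
            "size": int(arr.size),
            "median": float(np.median(arr)),
            "interval": bootstrap_interval(arr, level),
        }
    return out


_RANK_DISTANCES = {"footrule": spearman_footrule, "spearman": spearman_distance}


def _task_distance_matrix(per_task_rankings, distance: str) -> tuple[np.ndarray, list[str]]:
    mat = _as_rank_matrix(per_task_rankings)
    if distance not in _RANK_DISTANCES:
        raise ValueError(f"unknown rank distance {distance!r}")
    dist = _RANK_DISTANCES[distance]
    tasks = list(mat.index)
    m = len(tasks)
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d[i, j] = d[j, i] = dist(mat.iloc[i].to_numpy(), mat.iloc[j].to_numpy())
    return d, tasks


def dendrogram_data(per_task_rankings, distance: str = "footrule", agglomeration: str = "complete"):
    """Hierarchical clustering of tasks by ranking distance.

    Returns ``(linkage_matrix, task_labels)`` where the linkage matrix
    follows the scipy convention, built from the pairwise task distance
    matrix under the requested agglomeration (default: complete).
    """
    d, tasks = _task_distance_matrix(per_task_rankings, distance)
    if len(tasks) < 2:
        raise ValueError("need at least 2 tasks to cluster")
    linkage = hierarchy.linkage(squareform(d, checks=False), method=agglomeration)
    return linkage, tasks


def network_data(per_task_rankings, distance: str = "footrule", growth_rate: float = 0.05) -> nx.Graph:
    """Complete task graph with distance-driven target edge lengths.

    Edge (T_i, T_j) carries the raw ranking distance and a target
    length exp(growth_rate * distance), so large ranking discrepancies
    are accentuated exponentially.  Each node records the task's unique
    winner (first-ranked algorithm) or None when several algorithms
    share rank 1 — such nodes are drawn uncolored.
    """
    d, tasks = _task_distance_matrix(per_task_rankings, distance)
    if len(tasks) < 2:
        raise ValueError("need at least 2 tasks")
    mat = _as_rank_matrix(per_task_rankings)
    g = nx.Graph()
    for i, t in enumerate(tasks):
        row = mat.iloc[i]
        winners = row.index[row == row.min()]
        g.add_node(t, winner=winners[0] if len(winners) == 1 else None)
    for i in range(len(tasks)):
        for j in range(i + 1, len(tasks)):
            g.add_edge(
                tasks[i],
                tasks[j],
                distance=float(d[i, j]),
                length=float(np.exp(growth_rate * d[i, j])),
            )
    return g


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _palette(algs: list) -> dict:
    colors = sns.color_palette("husl", len(algs))
    return dict(zip(algs, colors))


def _marker_style(i: int) -> dict:
    # first ten algorithms: circles + solid; beyond: triangles + dashed
    return {"marker": "o", "linestyle": "-"} if i < 10 else {"marker": "v", "linestyle": "--"}


def _render_dot_box(data, ax, seed: int = 0, order=None, **_):
    slice_ = data
    algs = list(order) if order is not None else slice_.algorithms
    rng = np.random.default_rng(seed)
    vals = [slice_.values[a].to_numpy() for a in algs]
    ax.boxplot(vals, tick_labels=algs, showfliers=False)
    pal = _palette(algs)
    for i, (a, v) in enumerate(zip(algs, vals), start=1):
        jitter = rng.uniform(-0.18, 0.18, size=len(v))  # horizontal jitter only
        ax.scatter(i + jitter, v, s=12, alpha=0.6, color=pal[a], zorder=3)
    ax.set_xlabel("algorithm")
    ax.set_ylabel("metric value")


def _render_podium(data: PodiumData, ax, **_):
    p = len(data.algorithms)
    if p > PODIUM_ALGORITHM_LIMIT:
        raise ValueError(
            f"podium plot with {p} algorithms is unreadable (limit "
            f"{PODIUM_ALGORITHM_LIMIT}); truncate to a top list of algorithms first"
        )
    pal = _palette(data.algorithms)
    width = 1.0 / (p + 1)
    # spaghetti: each case is one line across the podium places
    for case in data.placements.index:
        xs, ys, cs = [], [], []
        for place in data.placements.columns:
            alg = data.placements.loc[case, place]
            col = data.algorithms.index(alg)
            xs.append((place - 1) + (col + 1) * width)
            ys.append(data.values.loc[case, alg])
            cs.append(pal[alg])
        ax.plot(xs, ys, color="0.8", lw=0.5, zorder=1)
        ax.scatter(xs, ys, c=cs, s=14, zorder=2)
    for place in data.placements.columns:
        ax.axvline(place - 0.0, color="0.9", lw=0.5)
    ax.set_xticks([pl - 0.5 for pl in data.placements.columns])
    ax.set_xticklabels([str(pl) for pl in data.placements.columns])
    ax.set_xlabel("podium place")
    ax.set_ylabel("metric value")
    # inset frequency bars along the bottom
    ymin = data.values.to_numpy().min()
    span = float(np.ptp(data.values.to_numpy())) or 1.0
    base = ymin - 0.18 * span
    for place in data.placements.columns:
        for col, alg in enumerate(data.algorithms):
            f = data.frequencies.loc[alg, place]
            ax.bar(
                (place - 1) + (col + 1) * width,
                f * 0.12 * span,
                width=width * 0.8,
                bottom=base,
                color=pal[alg],
            )
    ax.set_ylim(bottom=base - 0.02 * span)


def _render_heatmap(data: pd.DataFrame, ax, **_):
    sns.heatmap(data, ax=ax, annot=data.shape[1] <= 12, fmt="d", cmap="Blues", cbar=True)
    ax.set_xlabel("algorithm")
    ax.set_ylabel("rank")


def _render_line(data: pd.DataFrame, ax, **_):
    methods = list(data.columns)
    x = np.arange(len(methods))
    pal = _palette(list(data.index))
    for i, alg in enumerate(data.index):
        ax.plot(x, data.loc[alg], label=str(alg), color=pal[alg], **_marker_style(i))
    ax.set_xticks(x)
    ax.set_xticklabels(methods, rotation=30, ha="right")
    ax.invert_yaxis()
    ax.set_ylabel("rank")
    ax.legend(fontsize="small", ncols=2)


def _render_blob(data: dict, ax, **_):
    groups = list(data)
    pal = _palette(groups)
    for i, g in enumerate(groups):
        info = data[g]
        freq = info["frequencies"]
        rel = freq / info["size"]
        ax.scatter(
            np.full(len(freq), i),
            freq.index,
            s=2000 * rel.to_numpy(),  # blob area proportional to relative frequency
            color=pal[g],
            alpha=0.6,
            zorder=2,
        )
        lo, hi = info["interval"]
        ax.plot([i, i], [lo, hi], color="black", lw=1, zorder=3)
        ax.scatter([i], [info["median"]], marker="x", color="black", zorder=4)
    ax.set_xticks(range(len(groups)))
    ax.set_xticklabels([str(g) for g in groups], rotation=30, ha="right")
    ax.invert_yaxis()
    ax.set_ylabel("rank")


def _render_violin(data, ax, **_):
    tau = np.asarray(data, dtype=float)
    tau = tau[~np.isnan(tau)]
    if tau.size == 0:
        raise ValueError("no defined tau values to plot")
    sns.violinplot(y=tau, ax=ax, inner="box", cut=0)
    ax.set_ylabel("Kendall's tau to full-data ranking")


def _render_significance_map(data: SignificanceMatrix, ax, **_):
    inc = data.significant.astype(int)
    # yellow = significantly superior, blue = not
    sns.heatmap(
        inc.T,
        ax=ax,
        cmap=["#3b4cc0", "#f9d616"],
        cbar=False,
        linewidths=0.5,
        linecolor="white",
        vmin=0,
        vmax=1,
    )
    ax.set_xlabel("algorithm (superior)")
    ax.set_ylabel("algorithm (compared against)")


def _render_dendrogram(data, ax, **_):
    linkage, labels = data
    hierarchy.dendrogram(linkage, labels=labels, ax=ax)
    ax.set_ylabel("ranking distance (complete linkage)")


def _render_network(data: nx.Graph, ax, **_):
    g = data
    pos = nx.kamada_kawai_layout(g, dist={u: dict(d) for u, d in nx.shortest_path_length(g, weight="length")})
    winners = nx.get_node_attributes(g, "winner")
    unique = sorted({w for w in winners.values() if w is not None})
    pal = _palette(unique) if unique else {}
    colors = [pal.get(winners.get(n)) if winners.get(n) is not None else "white" for n in g.nodes]
    nx.draw_networkx_edges(g, pos, ax=ax, edge_color="0.7")
    nx.draw_networkx_nodes(g, pos, ax=ax, node_color=colors, edgecolors="black", node_size=600)
    nx.draw_networkx_labels(g, pos, ax=ax, font_size=8)
    if unique:
        handles = [plt.Line2D([], [], marker="o", ls="", color=pal[w], label=str(w)) for w in unique]
        ax.legend(handles=handles, title="task winner", fontsize="small")
    ax.set_axis_off()


_RENDERERS = {
    "dot_box": _render_dot_box,
    "podium": _render_podium,
    "heatmap": _render_heatmap,
    "line": _render_line,
    "blob": _render_blob,
    "violin": _render_violin,
    "significance_map": _render_significance_map,
    "dendrogram": _render_dendrogram,
    "network": _render_network,
}

FIGURE_KINDS = tuple(_RENDERERS)


def render(kind: str, data, path, figsize=(8, 5), title: str | None = None, **style):
    """Render computed figure data to an image file (PNG or SVG).

    ``kind`` is one of :data:`FIGURE_KINDS`; ``data`` is the output of
    the matching computation (or the raw object it documents).  The
    output is deterministic given data, seed and style.
    """
    if kind not in _RENDERERS:
        raise ValueError(f"unknown figure kind {kind!r}; choose from {FIGURE_KINDS}")
    fig, ax = plt.subplots(figsize=figsize)
    try:
        _RENDERERS[kind](data, ax, **style)
        if title:
            ax.set_title(title)
        fig.tight_layout()
        fig.savefig(path)
    finally:
        plt.close(fig)
    return path
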