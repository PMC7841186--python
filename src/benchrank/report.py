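"""End-to-end report generation: ingestion -> ranking -> stability -> figures.

`run_report` wires the whole analysis together for a challenge CSV:
per-task rankings under the configured method, a cross-task consensus
for multi-task challenges, bootstrap stability, significance maps, the
full figure family, and a single navigable Markdown document.  A saved
:class:`AnalysisConfig` plus the input CSV reproduces the entire
report bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from benchrank import viz
from benchrank.data_model import ChallengeData, load_challenge, impute_missing
from benchrank.rank_similarity import consensus_rank
from benchrank.ranking import METHOD_NAMES, make_ranker
from benchrank.significance import significance_matrix
from benchrank.stability import SMALL_N_CAUTION, bootstrap_rankings

__all__ = ["AnalysisConfig", "run_report"]

#: figure kinds produced for every task
SINGLE_TASK_FIGURES = ("dot_box", "podium", "heatmap", "line", "blob", "violin", "significance_map")
#: additional figure kinds for multi-task challenges
MULTI_TASK_FIGURES = ("task_blob", "algorithm_blob", "task_violins", "dendrogram", "network")


@dataclass
class AnalysisConfig:
    """Fully serializable configuration of one analysis run.

    Defaults follow common challenge practice: aggregate-then-rank with
    the mean, mean-rank consensus over per-task rankings, b = 1000
    bootstrap replicates, alpha = 0.05, 95% intervals.
    """

    method: str = "mean"  # one of METHOD_NAMES
    consensus_method: str = "mean"
    b: int = 1000
    seed: int = 1
    alpha: float = 0.05
    small_better: bool = False
    worst_value: float | None = None
    interval_level: float = 95.0
    top: int | None = None  # truncate figures to the top-k consensus algorithms
    figures: tuple = SINGLE_TASK_FIGURES + MULTI_TASK_FIGURES
    column_map: dict | None = None

    def __post_init__(self) -> None:
        if self.method not in METHOD_NAMES:
            raise ValueError(f"unknown ranking method {self.method!r}; choose from {METHOD_NAMES}")
        if self.b < 1:
            raise ValueError("b must be at least 1")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["figures"] = list(d["figures"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "figures" in d:
            d["figures"] = tuple(d["figures"])
        return cls(**d)


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the failing stage named."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"report stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_report(config: AnalysisConfig, input_path, out_dir) -> dict:
    """Run the full analysis for a challenge CSV and write a report.

    Writes per-task ranking tables, the consensus table (multi-task),
    bootstrap replicate/summary CSVs, significance matrices, all
    enabled figures, and ``report.md`` tying everything together.
    Returns a dict of the in-memory results keyed by stage.
    """
    out = Path(out_dir)
    fig_dir = out / "figures"
    tab_dir = out / "tables"
    fig_dir.mkdir(parents=True, exist_ok=True)
    tab_dir.mkdir(parents=True, exist_ok=True)

    with _stage("load"):
        data = load_challenge(input_path, column_map=config.column_map, small_better=config.small_better)
    with _stage("impute"):
        data = impute_missing(data, worst_value=config.worst_value)

    ranker = make_ranker(config.method, alpha=config.alpha)
    line_methods = {
        "mean": make_ranker("mean"),
        "median": make_ranker("median"),
        "rank-then-mean": make_ranker("rank-then-mean"),
        "significance": make_ranker("significance", alpha=config.alpha),
    }

    tasks = data.tasks
    multi = len(tasks) > 1
    results: dict = {"config": config, "data": data, "tasks": {}}
    rankings = {}
    boots = {}
    cautions = []
    lines = [
        "# Challenge analysis report",
        "",
        f"- ranking method: `{config.method}`; bootstrap replicates: b={config.b}; "
        f"alpha={config.alpha}; seed={config.seed}",
        f"- metric direction: {'smaller' if config.small_better else 'larger'} is better",
        "",
        "## Data",
        "",
        "```",
        data.validation_report(),
        "```",
        "",
    ]

    for ti, task in enumerate(tasks):
        with _stage(f"rank[{task}]"):
            sl = data.task_slice(task)
            ranking = ranker(sl)
        rankings[task] = ranking
        ranking.to_csv(tab_dir / f"ranking_{task}.csv")

        with _stage(f"bootstrap[{task}]"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                boot = bootstrap_rankings(sl, method=ranker, b=config.b, seed=config.seed + ti)
        boots[task] = boot
        boot.to_csv(tab_dir / f"bootstrap_{task}_replicates.csv", tab_dir / f"bootstrap_{task}_summary.csv")
        if boot.small_n_caution:
            cautions.append(
                f"task {task}: only {sl.n_cases} test cases (< {SMALL_N_CAUTION}); "
                "treat bootstrap results with caution"
            )

        with _stage(f"significance[{task}]"):
            sig = significance_matrix(sl, alpha=config.alpha, small_better=config.small_better)
        sig.to_csv(tab_dir / f"significance_{task}.csv")

        order = ranking.ordered()
        if config.top:
            order = order[: config.top]
        sub = type(sl)(sl.task_id, sl.values[order], sl.small_better)

        figures = {}
        with _stage(f"figures[{task}]"):
            if "dot_box" in config.figures:
                figures["dot_box"] = viz.render(
                    "dot_box", sub, fig_dir / f"{task}_dot_box.png", seed=config.seed, order=order,
                    title=f"{task}: metric values",
                )
            if "podium" in config.figures and len(order) <= viz.PODIUM_ALGORITHM_LIMIT:
                pod = viz.podium_data(sub, seed=config.seed)
                figures["podium"] = viz.render("podium", pod, fig_dir / f"{task}_podium.png",
                                               title=f"{task}: podium")
            if "heatmap" in config.figures:
                hm = viz.heatmap_counts(sub)
                figures["heatmap"] = viz.render("heatmap", hm, fig_dir / f"{task}_heatmap.png",
                                                title=f"{task}: per-case ranks")
            if "line" in config.figures:
                ln = viz.line_plot_data(sub, line_methods).loc[order]
                figures["line"] = viz.render("line", ln, fig_dir / f"{task}_line.png",
                                             title=f"{task}: ranking-method robustness")
            if "blob" in config.figures:
                samples = {a: boot.replicate_ranks[a].to_numpy() for a in order if a in boot.replicate_ranks}
                bd = viz.blob_data(samples, level=config.interval_level)
                figures["blob"] = viz.render("blob", bd, fig_dir / f"{task}_blob.png",
                                             title=f"{task}: bootstrap rank stability")
            if "violin" in config.figures and not np.all(np.isnan(boot.tau)):
                figures["violin"] = viz.render("violin", boot.tau, fig_dir / f"{task}_violin.png",
                                               title=f"{task}: tau to full-data ranking")
            if "significance_map" in config.figures:
                sig_ord = significance_matrix(sub, alpha=config.alpha, small_better=config.small_better)
                figures["significance_map"] = viz.render(
                    "significance_map", sig_ord, fig_dir / f"{task}_significance_map.png",
                    title=f"{task}: pairwise superiority",
                )

        results["tasks"][task] = {"ranking": ranking, "bootstrap": boot, "significance": sig}
        lines += [f"## Task {task}", "", "```", ranking.to_frame().to_string(), "```", ""]
        lines += [f"![{k}](figures/{Path(p).name})\n" for k, p in figures.items()]

    if multi:
        with _stage("consensus"):
            consensus = consensus_rank(rankings, method=config.consensus_method)
        consensus.to_csv(tab_dir / "consensus.csv")
        results["consensus"] = consensus
        order = consensus.ordered()
        if config.top:
            order = order[: config.top]
        lines += ["## Consensus across tasks", "", "```", consensus.to_frame().to_string(), "```", ""]

        with _stage("multi-task figures"):
            if "task_blob" in config.figures:
                samples = {a: consensus.rank_matrix[a].to_numpy() for a in order}
                viz.render("blob", viz.blob_data(samples), fig_dir / "tasks_blob.png",
                           title="rank distribution across tasks")
                lines.append("![task blob](figures/tasks_blob.png)\n")
            if "algorithm_blob" in config.figures:
                for alg in order:
                    samples = {t: boots[t].replicate_ranks[alg].to_numpy() for t in tasks}
                    viz.render("blob", viz.blob_data(samples), fig_dir / f"algorithm_blob_{alg}.png",
                               title=f"{alg}: bootstrap ranks per task")
                lines.append(f"Per-algorithm bootstrap blob plots: {', '.join(order)}\n")
            if "task_violins" in config.figures:
                for t in tasks:
                    if not np.all(np.isnan(boots[t].tau)):
                        viz.render("violin", boots[t].tau, fig_dir / f"violin_{t}.png",
                                   title=f"{t}: tau distribution")
                lines.append("Per-task violin plots written to figures/.\n")
            if "dendrogram" in config.figures:
                dd = viz.dendrogram_data(rankings)
                viz.render("dendrogram", dd, fig_dir / "dendrogram.png", title="task clustering")
                lines.append("![dendrogram](figures/dendrogram.png)\n")
            if "network" in config.figures:
                net = viz.network_data(rankings)
                viz.render("network", net, fig_dir / "network.png", title="task similarity network")
                lines.append("![network](figures/network.png)\n")

    if cautions:
        lines += ["## Cautions", ""] + [f"- {c}" for c in cautions] + [""]
    if data.n_imputed:
        lines += [
            f"Imputed {data.n_imputed} missing cells; imputed values participate in "
            "rankings and significance tests alike.",
            "",
        ]
    lines += [f"Seeds: analysis seed {config.seed} (bootstrap per task: seed + task index).", ""]

    config.to_yaml(out / "config.yaml")
    (out / "report.md").write_text("\n".join(lines))
    results["report_path"] = out / "report.md"
    return results
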