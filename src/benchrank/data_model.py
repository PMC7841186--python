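"""Assessment-data container, CSV ingestion, validation and imputation.

The central object is :class:`ChallengeData`: a long-format table of
per-test-case metric values, one row per (task, algorithm, case) triple,
together with the metric direction.  A challenge with *m* tasks, *p*
algorithms and *n_k* test cases per task is fully described by such a
table.  Algorithms that fail to produce a value for some test case are
handled by imputing an unfavorable value (e.g. 0 for a non-negative
larger-is-better metric such as the Dice similarity coefficient), so
that every ranking sees a complete cases x algorithms matrix per task.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["ChallengeData", "TaskSlice", "load_challenge", "impute_missing"]

#: default CSV column names, overridable through ``column_map``
DEFAULT_COLUMNS = {"task": "task", "algorithm": "algorithm", "case": "case", "value": "value"}

#: task label assigned to single-task files that carry no task column
IMPLICIT_TASK = "T1"


@dataclass(frozen=True)
class TaskSlice:
    """Complete cases x algorithms metric matrix for one task.

    Attributes
    ----------
    task_id:
        Task label.
    values:
        DataFrame indexed by case id with one column per algorithm.
        After imputation the matrix contains no missing cells.
    small_better:
        True if smaller metric values indicate better performance.
    """

    task_id: str
    values: pd.DataFrame
    small_better: bool = False

    @property
    def algorithms(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_cases(self) -> int:
        return len(self.values)

    def is_complete(self) -> bool:
        return not self.values.isna().any().any()

    def resample(self, case_positions: np.ndarray) -> "TaskSlice":
        """Return a bootstrap resample keeping case multiplicity.

        A case drawn twice appears twice and contributes twice to every
        aggregate and every paired test.
        """
        sub = self.values.iloc[np.asarray(case_positions)]
        sub = sub.set_axis(range(len(sub)), axis=0)
        return TaskSlice(self.task_id, sub, self.small_better)


@dataclass
class ChallengeData:
    """Long-format challenge assessment data.

    Attributes
    ----------
    records:
        DataFrame with columns ``task``, ``algorithm``, ``case``,
        ``value``; at most one row per (task, algorithm, case) triple.
        ``value`` may contain NaN before imputation.
    small_better:
        Metric-direction flag, global for the analysis run.
    n_imputed:
        Number of cells filled by :func:`impute_missing` (0 before).
    imputed_value:
        Per-task value used for imputation, populated by
        :func:`impute_missing`.
    """

    records: pd.DataFrame
    small_better: bool = False
    n_imputed: int = 0
    imputed_value: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = ["task", "algorithm", "case", "value"]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise ValueError(f"records is missing required columns: {missing}")
        dup = self.records.duplicated(subset=["task", "algorithm", "case"])
        if dup.any():
            triple = self.records.loc[dup.idxmax(), ["task", "algorithm", "case"]]
            raise ValueError(
                "duplicate (task, algorithm, case) triple: "
                f"({triple['task']!r}, {triple['algorithm']!r}, {triple['case']!r})"
            )

    @property
    def tasks(self) -> list[str]:
        return list(pd.unique(self.records["task"]))

    @property
    def algorithms(self) -> list[str]:
        return sorted(pd.unique(self.records["algorithm"]))

    def algorithms_in(self, task: str) -> list[str]:
        mask = self.records["task"] == task
        return sorted(pd.unique(self.records.loc[mask, "algorithm"]))

    def cases_in(self, task: str) -> list[str]:
        mask = self.records["task"] == task
        return list(pd.unique(self.records.loc[mask, "case"]))

    def is_complete(self) -> bool:
        """True if every task is a full grid of finite values."""
        if self.records["value"].isna().any():
            return False
        for task in self.tasks:
            sub = self.records[self.records["task"] == task]
            if len(sub) != sub["algorithm"].nunique() * sub["case"].nunique():
                return False
        return True

    def task_slice(self, task: str) -> TaskSlice:
        """Pivot one task into a cases x algorithms matrix."""
        sub = self.records[self.records["task"] == task]
        if sub.empty:
            raise KeyError(f"unknown task {task!r}")
        mat = sub.pivot(index="case", columns="algorithm", values="value")
        mat = mat.loc[self.cases_in(task), self.algorithms_in(task)]
        mat.columns.name = None
        mat.index.name = "case"
        return TaskSlice(task, mat, self.small_better)

    def to_csv(self, path) -> None:
        """Write the long-format table in the schema read by
        :func:`load_challenge` (columns task, algorithm, case, value)."""
        self.records.to_csv(path, index=False)

    def validation_report(self) -> str:
        """Plain-text summary of structure, imputations and exclusions."""
        lines = [
            f"tasks: {len(self.tasks)}",
            f"algorithms: {len(self.algorithms)}",
        ]
        for task in self.tasks:
            algs = self.algorithms_in(task)
            lines.append(f"task {task}: {len(self.cases_in(task))} cases, {len(algs)} algorithms")
            absent = sorted(set(self.algorithms) - set(algs))
            if absent:
                lines.append(
                    f"  excluded from task {task} (no records at all): {', '.join(absent)}"
                )
        if self.n_imputed:
            per_task = ", ".join(f"{t}={v:g}" for t, v in self.imputed_value.items())
            lines.append(f"imputed cells: {self.n_imputed} (worst value per task: {per_task})")
            lines.append("note: imputed values enter rankings and significance tests alike")
        else:
            lines.append("imputed cells: 0")
        return "\n".join(lines)


def load_challenge(
    path,
    column_map: dict[str, str] | None = None,
    small_better: bool = False,
) -> ChallengeData:
    """Read long-format challenge assessment data from a CSV file.

    Parameters
    ----------
    path:
        CSV file with one row per (task, algorithm, case) metric value.
        UTF-8, ``.`` decimal separator.
    column_map:
        Maps the canonical names ``task``, ``algorithm``, ``case``,
        ``value`` to the file's column headers.  Defaults to those very
        names.  A file without a task column (``task`` omitted from the
        map and absent from the header) is treated as a single-task
        challenge with implicit task ``"T1"``.
    small_better:
        Metric-direction flag.

    Raises
    ------
    ValueError
        On a duplicate (task, algorithm, case) triple (named in the
        message) or an unparseable metric value (with its row number).
    """
    colmap = dict(DEFAULT_COLUMNS)
    if column_map:
        colmap.update(column_map)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")

    for key in ("algorithm", "case", "value"):
        if colmap[key] not in raw.columns:
            raise ValueError(f"column {colmap[key]!r} (for {key!r}) not found in {path}")

    df = pd.DataFrame(
        {
            "algorithm": raw[colmap["algorithm"]].str.strip(),
            "case": raw[colmap["case"]].str.strip(),
        }
    )
    if colmap["task"] in raw.columns:
        df.insert(0, "task", raw[colmap["task"]].str.strip())
    else:
        df.insert(0, "task", IMPLICIT_TASK)

    text = raw[colmap["value"]].str.strip()
    values = pd.to_numeric(text, errors="coerce")
    bad = values.isna() & (text != "") & text.notna() & ~text.str.lower().isin(["na", "nan"])
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        # +2: one for the header line, one for 1-based numbering
        raise ValueError(f"unparseable metric value {text.iloc[row]!r} at row {row + 2} of {path}")
    df["value"] = values.astype(float)
    return ChallengeData(df.reset_index(drop=True), small_better=small_better)


def impute_missing(data: ChallengeData, worst_value: float | None = None) -> ChallengeData:
    """Fill missing per-case values with an unfavorable constant.

    For every task, every algorithm that participates in that task (has
    at least one record there) receives ``worst_value`` for each case it
    is missing — whether the cell is absent from the table or recorded
    as NaN.  Algorithms entirely absent from a task are *not* invented:
    they are excluded from that task's ranking and flagged in the
    validation report.

    Parameters
    ----------
    worst_value:
        Imputation constant.  Defaults to 0 for a larger-is-better
        metric and to the observed per-task maximum for a
        smaller-is-better metric.

    Returns
    -------
    ChallengeData
        New object with a complete grid per task; ``n_imputed`` counts
        the filled cells.  Imputing twice is a no-op the second time.
    """
    if worst_value is not None and not np.isfinite(worst_value):
        raise ValueError("worst_value must be finite")

    frames = []
    n_imputed = 0
    imputed_value: dict[str, float] = {}
    for task in data.tasks:
        sub = data.records[data.records["task"] == task]
        if worst_value is None:
            if data.small_better:
                observed = sub["value"].dropna()
                fill = float(observed.max()) if len(observed) else 0.0
            else:
                fill = 0.0
        else:
            fill = float(worst_value)
        if len(sub) == sub["case"].nunique() * sub["algorithm"].nunique() and not sub[
            "value"
        ].isna().any():
            frames.append(sub)  # already complete: keep rows untouched
            continue
        grid = pd.MultiIndex.from_product(
            [pd.unique(sub["case"]), pd.unique(sub["algorithm"])], names=["case", "algorithm"]
        )
        full = (
            sub.set_index(["case", "algorithm"])["value"].reindex(grid).reset_index()
        )
        missing = full["value"].isna()
        n_imputed += int(missing.sum())
        if missing.any():
            imputed_value[task] = fill
            full.loc[missing, "value"] = fill
        full.insert(0, "task", task)
        frames.append(full[["task", "algorithm", "case", "value"]])

    out = pd.concat(frames, ignore_index=True)
    return replace(
        data,
        records=out,
        n_imputed=data.n_imputed + n_imputed,
        imputed_value={**data.imputed_value, **imputed_value},
    )
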