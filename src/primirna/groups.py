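"""Group-level evaluation of differential expression.

Three pieces: the detection filter (a pri-miRNA is "detected" in an
experiment when its counts summed over that experiment's libraries
reach a minimum, default 4 reads); one-sided Wilcoxon rank-sum tests
asking whether each positional group's log2 fold-changes are shifted
above a background set; and 2x2 up/down contingency tables comparing
the direction of change of the common detected pri-miRNAs across two
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import GroupLabel, PriMiRNAModel
from .counting import CountMatrix


def detection_filter(
    counts: CountMatrix | pd.DataFrame,
    feature_subset: Iterable[str] | None = None,
    *,
    min_total: int = 4,
) -> set[str]:
    """Features whose counts summed across the matrix's libraries reach
    ``min_total`` (default 4 accumulated reads), optionally restricted
    to ``feature_subset``."""
    frame = counts.counts if isinstance(counts, CountMatrix) else counts
    if feature_subset is not None:
        wanted = [f for f in frame.index if f in set(feature_subset)]
        frame = frame.loc[wanted]
    totals = frame.sum(axis=1)
    return set(totals.index[totals >= min_total])


def wilcoxon_greater(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum test (alternative: x shifted above y).

    Returns the rank-sum statistic of ``x`` in the pooled midrank
    ranking and the p-value: exact by enumeration when the pooled size
    is at most 20 with no ties, otherwise the normal approximation with
    tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="greater", method=method,
                             use_continuity=True)
    rank_sum = float(res.statistic) + x.size * (x.size + 1) / 2.0
    return rank_sum, float(res.pvalue)


@dataclass(slots=True)
class GroupTestResult:
    group: GroupLabel
    n_group: int
    n_background: int
    statistic: float
    pvalue: float
    direction: str = "greater"


def group_shift_tests(
    de: pd.DataFrame,
    models: Iterable[PriMiRNAModel] | Mapping[str, GroupLabel],
    background_ids: Iterable[str],
) -> tuple[list[GroupTestResult], list[str]]:
    """Per-group one-sided shift tests of log2FC against a background.

    ``de`` is an exact-test result table indexed by feature id with a
    ``log2FC`` column; ``models`` supplies the group of each pri-miRNA
    feature; ``background_ids`` (e.g. all protein-coding genes in the
    table) must be disjoint from the model ids. Groups with no member
    present in ``de`` are skipped with a note, not an error.
    """
    if isinstance(models, Mapping):
        group_of = dict(models)
    else:
        group_of = {m.id: m.group for m in models}
    background = [b for b in background_ids if b in de.index]
    if set(background) & set(group_of):
        raise ValueError("background overlaps the pri-miRNA model set")
    if not background:
        raise ValueError("background set is empty")
    y = de.loc[background, "log2FC"].to_numpy(float)

    results: list[GroupTestResult] = []
    notes: list[str] = []
    order = [GroupLabel.G1, GroupLabel.G2, GroupLabel.G3A, GroupLabel.G3B, GroupLabel.G4]
    for g in order:
        ids = [fid for fid, grp in group_of.items() if grp is g and fid in de.index]
        if not ids:
            notes.append(f"{g.value}: no members in the DE table, skipped")
            continue
        xs = de.loc[ids, "log2FC"].to_numpy(float)
        stat, p = wilcoxon_greater(xs, y)
        results.append(GroupTestResult(g, len(ids), len(background), stat, p))
    return results, notes


def group_tests_frame(results: list[GroupTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": r.group.value,
                "n_group": r.n_group,
                "n_background": r.n_background,
                "rank_sum": r.statistic,
                "pvalue": r.pvalue,
                "alternative": r.direction,
            }
            for r in results
        ]
    ).set_index("group")


@dataclass
class ContingencyTable:
    """2x2 up/down table of common features across two experiments.

    Rows: direction in experiment A; columns: direction in experiment
    B. ``n_common`` counts the features entering the table, so
    ``cells.sum() == n_common - n_zero_excluded - n_missing``.
    """

    cells: np.ndarray  # [[A_up&B_up, A_up&B_down], [A_down&B_up, A_down&B_down]]
    n_common: int
    n_zero_excluded: int = 0
    n_missing: int = 0
    label_a: str = "A"
    label_b: str = "B"

    def validate(self) -> None:
        if int(self.cells.sum()) != self.n_common - self.n_zero_excluded - self.n_missing:
            raise ValueError("contingency cells do not conserve the common feature count")

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.cells,
            index=pd.Index([f"{self.label_a}_up", f"{self.label_a}_down"]),
            columns=pd.Index([f"{self.label_b}_up", f"{self.label_b}_down"]),
        )
        frame["row_total"] = frame.sum(axis=1)
        frame.loc["col_total"] = frame.sum(axis=0)
        return frame


def cross_tabulate(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    common_ids: Iterable[str],
    *,
    fdr_filter_a: float | None = None,
    label_a: str = "A",
    label_b: str = "B",
) -> ContingencyTable:
    """Tabulate direction of change of common features in two experiments.

    Each feature is classified up (log2FC > 0) or down (< 0) in each
    experiment; exact zeros are excluded and tallied. With
    ``fdr_filter_a`` the common set is first restricted to features
    significant in experiment A at that FDR.
    """
    ids = sorted(set(common_ids))
    if fdr_filter_a is not None:
        ids = [f for f in ids if f in de_a.index and de_a.loc[f, "fdr"] < fdr_filter_a]
    cells = np.zeros((2, 2), dtype=int)
    n_zero = n_missing = 0
    for fid in ids:
        if fid not in de_a.index or fid not in de_b.index:
            n_missing += 1
            continue
        fa = float(de_a.loc[fid, "log2FC"])
        fb = float(de_b.loc[fid, "log2FC"])
        if not (np.isfinite(fa) and np.isfinite(fb)):
            n_missing += 1
            continue
        if fa == 0.0 or fb == 0.0:
            n_zero += 1
            continue
        cells[0 if fa > 0 else 1, 0 if fb > 0 else 1] += 1
    table = ContingencyTable(
        cells=cells,
        n_common=len(ids),
        n_zero_excluded=n_zero,
        n_missing=n_missing,
        label_a=label_a,
        label_b=label_b,
    )
    table.validate()
    return table
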