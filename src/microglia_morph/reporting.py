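"""Population-composition tables and between-group comparisons.

After classification, each treatment group (e.g. control, NMDA, NMDA+LPS) is
summarised as counts of cells per morphology class plus ``unassigned``.
Group compositions are compared with Pearson's chi-squared test on the count
table; for several treatment groups each is compared pairwise against a
reference with Benjamini–Hochberg adjusted p-values.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .classification import UNASSIGNED
from .synthetic import MORPHOLOGY_CLASSES

__all__ = ["compose", "compare_compositions", "compare_all_groups"]

_COLUMNS = list(MORPHOLOGY_CLASSES) + [UNASSIGNED]


def compose(assignments: pd.DataFrame, group_column: str = "group",
            class_column: str = "assigned_class"):
    """Count cells per (group, morphology class).

    Returns ``(counts, percentages)``: two DataFrames with one row per group
    and one column per class plus ``unassigned``.  Percentages sum to 100
    per group.  Empty groups are omitted with a warning.
    """
    for col in (group_column, class_column):
        if col not in assignments.columns:
            raise ValueError(f"assignments lack column {col!r}")
    present_groups = assignments[group_column].dropna().unique()
    empty = assignments[group_column].isna().sum()
    if empty:
        warnings.warn(f"{empty} assignments without a group tag were omitted",
                      stacklevel=2)
    counts = pd.crosstab(assignments[group_column],
                         assignments[class_column])
    counts = counts.reindex(columns=_COLUMNS, fill_value=0)
    counts = counts.loc[[g for g in present_groups if g in counts.index]]
    counts.index.name = "group"
    counts.columns.name = None
    totals = counts.sum(axis=1)
    nonempty = totals > 0
    if (~nonempty).any():
        warnings.warn(
            f"empty groups omitted: {list(counts.index[~nonempty])}",
            stacklevel=2)
    counts = counts[nonempty]
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return counts, pct


def compare_compositions(counts: pd.DataFrame, group_a: str, group_b: str):
    """Pearson chi-squared test between two composition rows.

    Classes absent from both groups (zero column totals would give zero
    expected counts) are pooled out before the test; the dropped classes are
    reported in the result.  Returns a dict with ``statistic``, ``df``,
    ``p_value`` and ``pooled_out``.
    """
    for g in (group_a, group_b):
        if g not in counts.index:
            raise ValueError(f"group {g!r} not present in the table")
    table = counts.loc[[group_a, group_b]].to_numpy(dtype=float)
    col_names = list(counts.columns)
    nonzero = table.sum(axis=0) > 0
    pooled_out = [c for c, nz in zip(col_names, nonzero) if not nz]
    table = table[:, nonzero]
    if table.shape[1] < 2:
        raise ValueError("chi-squared needs at least two non-empty classes "
                         "(df would be 0)")
    res = stats.chi2_contingency(table, correction=False)
    return dict(statistic=float(res.statistic), df=int(res.dof),
                p_value=float(res.pvalue), pooled_out=pooled_out)


def compare_all_groups(counts: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Pairwise chi-squared of every group against ``reference``.

    P-values are Benjamini–Hochberg adjusted across the comparisons.
    """
    others = [g for g in counts.index if g != reference]
    if not others:
        raise ValueError("nothing to compare: only the reference group present")
    rows = []
    for g in others:
        r = compare_compositions(counts, reference, g)
        rows.append(dict(group=g, statistic=r["statistic"], df=r["df"],
                         p_value=r["p_value"]))
    out = pd.DataFrame(rows)
    out["adj_p_value"] = _benjamini_hochberg(out["p_value"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out
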