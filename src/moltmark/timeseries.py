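"""Day grouping, daily summaries and fold-change statistics.

The time-series design samples three replicate pools per day early in the
stage, but replication thins near the terminal molt, so trailing days are
combined into two-day groups (defaults: 11-12 and 13-14, labelled by their
midpoints 11.5 and 13.5) and days past the median stage duration (15-16)
are excluded.  Summaries (mean/min/max per day group per gene) and log2
fold changes between day groups follow the convention that a positive fold
change means higher expression later in the molt cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = [
    "DayGroupingRules",
    "apply_grouping",
    "daily_summary",
    "logfc_between_days",
    "range_fc",
]


@dataclass(frozen=True)
class DayGroupingRules:
    """Which days are merged into one group and which are dropped."""

    combine: tuple[frozenset[float], ...] = (
        frozenset({11.0, 12.0}),
        frozenset({13.0, 14.0}),
    )
    exclude: frozenset[float] = frozenset({15.0, 16.0})

    def __post_init__(self) -> None:
        combine = tuple(frozenset(float(d) for d in s) for s in self.combine)
        exclude = frozenset(float(d) for d in self.exclude)
        object.__setattr__(self, "combine", combine)
        object.__setattr__(self, "exclude", exclude)
        seen: set[float] = set()
        for s in combine:
            if s & seen:
                raise ValueError("combined day-sets must be disjoint")
            seen |= s
        if exclude & seen:
            raise ValueError("excluded days must not appear in combined sets")

    def group_of(self, day: float) -> float | None:
        """Numeric day-group label for a day, or None if the day is excluded.

        Combined sets are labelled by their midpoint so groups keep a
        natural temporal position.
        """
        day = float(day)
        if day in self.exclude:
            return None
        for s in self.combine:
            if day in s:
                return float(np.mean(sorted(s)))
        return day


def apply_grouping(matrix: ExpressionMatrix, rules: DayGroupingRules) -> ExpressionMatrix:
    """Drop excluded days and attach a ``day_group`` label per sample."""
    groups = matrix.samples["day"].map(rules.group_of)
    keep = groups.notna()
    if not keep.any():
        raise ValueError("empty matrix: all days excluded by grouping rules")
    samples = matrix.samples.loc[keep].copy()
    samples["day_group"] = groups.loc[keep].astype(float)
    return replace(matrix, values=matrix.values.loc[keep].copy(), samples=samples)


def daily_summary(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Mean, min, max and n of log2 expression per (day group, gene).

    Statistics for a combined group are computed over the union of its
    constituent days' samples.
    """
    long = matrix.values.copy()
    long["day_group"] = matrix.day_groups
    melted = long.melt(id_vars="day_group", var_name="gene", value_name="log2_value")
    out = (
        melted.groupby(["day_group", "gene"], sort=True)["log2_value"]
        .agg(mean="mean", min="min", max="max", n="size")
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out


def _group_means(matrix: ExpressionMatrix) -> pd.DataFrame:
    return matrix.values.groupby(matrix.day_groups).mean()


def logfc_between_days(
    matrix: ExpressionMatrix, day_a: float, day_b: float
) -> pd.Series:
    """Per-gene log2 fold change between two day groups (later minus earlier).

    ``day_a`` is the earlier day, so genes more expressed late get positive
    values.
    """
    means = _group_means(matrix)
    for d in (day_a, day_b):
        if float(d) not in means.index:
            raise KeyError(f"day group {d} absent from matrix")
    fc = means.loc[float(day_b)] - means.loc[float(day_a)]
    fc.name = f"log2fc_{day_a:g}_to_{day_b:g}"
    return fc


def range_fc(matrix: ExpressionMatrix) -> pd.Series:
    """Per-gene untransformed fold change between min and max day-group means.

    Uses daily aggregate means (not individual replicates) as the observed
    expression values; always >= 1, and equals 1 only for a gene whose group
    means are all identical.
    """
    means = _group_means(matrix)
    fc = np.exp2(means.max(axis=0) - means.min(axis=0))
    fc.name = "range_fc"
    return fc
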