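"""Exhaustive pairwise expression-ratio screen for a stage discriminator.

Within a sample, the log2 ratio of two genes is the difference of their
stored log2 quantities, so it is identical on normalized and un-normalized
data (the per-sample normalization factor cancels).  The screen computes,
for every unordered pair of target genes, the pooled-variance Student's
t-statistic contrasting the per-sample ratios between a late and an early
period of the molt cycle, ranks pairs by the statistic, and applies a
Bonferroni-adjusted significance cutoff over the number of pairs.

The reported orientation puts the late-high gene in the numerator, so the
top-ranked pair reads as "high numerator/denominator ratio indicates late
molt stage".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .stats import pooled_t

__all__ = [
    "RatioScreenConfig",
    "RatioScreenResult",
    "pair_count",
    "sample_log_ratio",
    "bonferroni_alpha",
    "screen",
]

DEFAULT_EARLY = frozenset({1.0, 2.0, 3.0, 4.0, 5.0})
DEFAULT_LATE = frozenset({10.0, 11.5, 13.5})


@dataclass(frozen=True)
class RatioScreenConfig:
    """Periods, family alpha and orientation rule of the screen."""

    alpha: float = 0.05
    early_period: frozenset[float] = DEFAULT_EARLY
    late_period: frozenset[float] = DEFAULT_LATE

    def __post_init__(self) -> None:
        object.__setattr__(self, "early_period", frozenset(float(d) for d in self.early_period))
        object.__setattr__(self, "late_period", frozenset(float(d) for d in self.late_period))
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not self.early_period or not self.late_period:
            raise ValueError("periods must be non-empty")
        if self.early_period & self.late_period:
            raise ValueError("early and late periods must be disjoint")


@dataclass(frozen=True)
class RatioScreenResult:
    """One oriented gene pair of the screen, ranked by discriminating power."""

    numerator_gene: str
    denominator_gene: str
    t: float
    p: float
    bonferroni_alpha: float
    significant: bool
    mean_log2_ratio_early: float
    mean_log2_ratio_late: float
    rank: int
    degenerate: bool = False  # zero pooled variance with nonzero mean difference


def pair_count(n_genes: int) -> int:
    """Number of unordered gene pairs, n(n-1)/2."""
    if n_genes < 2:
        raise ValueError("need at least 2 genes to form a pair")
    return n_genes * (n_genes - 1) // 2


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Family-wise error cutoff alpha/m for m simultaneous tests."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return alpha / m


def sample_log_ratio(
    matrix: ExpressionMatrix, sample_id: str, gene_a: str, gene_b: str
) -> float:
    """Within-sample log2 expression ratio of gene_a over gene_b."""
    for g in (gene_a, gene_b):
        if g not in matrix.values.columns:
            raise KeyError(f"gene {g!r} absent from matrix")
    row = matrix.values.loc[sample_id]
    return float(row[gene_a] - row[gene_b])


def screen(
    matrix: ExpressionMatrix,
    config: RatioScreenConfig | None = None,
    genes: Sequence[str] | None = None,
) -> list[RatioScreenResult]:
    """Run the full pairwise ratio screen; returns results ranked by t.

    Housekeeping genes never enter the pair set: by default the pair set is
    ``matrix.target_genes``.  Within-sample ratios make the screen invariant
    to housekeeping normalization, so either matrix state is accepted.
    """
    config = config or RatioScreenConfig()
    genes = list(matrix.target_genes if genes is None else genes)
    m = pair_count(len(genes))
    cutoff = bonferroni_alpha(config.alpha, m)

    day_group = matrix.day_groups.astype(float)
    early_ids = day_group.index[day_group.isin(config.early_period)]
    late_ids = day_group.index[day_group.isin(config.late_period)]
    if len(early_ids) < 2 or len(late_ids) < 2:
        raise ValueError(
            f"each period needs >=2 samples, got early={len(early_ids)}, late={len(late_ids)}"
        )
    early = matrix.values.loc[early_ids, genes].to_numpy(dtype=float)
    late = matrix.values.loc[late_ids, genes].to_numpy(dtype=float)

    results = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            re_ = early[:, i] - early[:, j]
            rl = late[:, i] - late[:, j]
            t, p, _df, degenerate = pooled_t(rl, re_)
            num, den = genes[i], genes[j]
            if t < 0:  # orient so the late-high gene is the numerator
                num, den = den, num
                t = -t
                re_, rl = -re_, -rl
            results.append(
                RatioScreenResult(
                    numerator_gene=num,
                    denominator_gene=den,
                    t=t,
                    p=p,
                    bonferroni_alpha=cutoff,
                    significant=p < cutoff,
                    mean_log2_ratio_early=float(re_.mean()),
                    mean_log2_ratio_late=float(rl.mean()),
                    rank=0,
                    degenerate=degenerate,
                )
            )
    results.sort(key=lambda r: (-r.t, r.numerator_gene, r.denominator_gene))
    return [
        RatioScreenResult(**{**vars(r), "rank": k + 1}) for k, r in enumerate(results)
    ]


def screen_table(results: Sequence[RatioScreenResult]) -> pd.DataFrame:
    """Results as a DataFrame (one row per pair, ranked)."""
    return pd.DataFrame([vars(r) for r in results]).set_index("rank")
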