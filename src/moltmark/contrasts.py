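"""Two-group gene-wise contrasts and cross-platform fold-change concordance.

Covers the pre/post-apolysis comparison (per-gene Student's t-tests at a
nominal p < 0.05, no multiplicity correction — twelve candidate genes were
screened individually in the original design) and the Pearson correlation
of log2 fold changes measured by two platforms (RNA-seq counts vs qPCR)
for the same day-3 vs day-10 contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .stats import pooled_t, t_sf_two_sided

__all__ = [
    "GroupTestResult",
    "ConcordanceResult",
    "student_t",
    "apolysis_compare",
    "concordance",
    "load_crossplatform_fold_changes",
]

#: packaged fixture of day3-vs-day10 fold changes measured on both platforms
_FIXTURE = "crossplatform_fold_changes.tsv"


@dataclass(frozen=True)
class GroupTestResult:
    """Per-gene two-group contrast."""

    gene: str
    group_sizes: tuple[int, int]
    t: float
    p: float
    significant: bool  # at nominal 0.05
    direction: int  # sign of (group2 mean - group1 mean)


@dataclass(frozen=True)
class ConcordanceResult:
    """Pearson correlation of two paired per-gene fold-change vectors."""

    n: int
    r: float
    r_squared: float
    p: float


def student_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float, int]:
    """Pooled-variance Student's t of group_a vs group_b; two-sided p."""
    t, p, df, _ = pooled_t(group_a, group_b)
    return t, p, df


def apolysis_compare(
    matrix: ExpressionMatrix, alpha: float = 0.05
) -> tuple[list[GroupTestResult], list[GroupTestResult]]:
    """Per-gene pre- vs post-apolysis t-tests.

    Returns ``(all_results, significant_results)`` where the second list
    retains genes with p < ``alpha``.  ``direction`` is the sign of the
    post-minus-pre mean difference, so +1 means expression increases across
    apolysis.
    """
    phase = matrix.samples["molt_phase"]
    if phase.isna().all():
        raise ValueError("matrix has no molt_phase labels")
    pre_ids = phase.index[phase == "pre"]
    post_ids = phase.index[phase == "post"]
    if len(pre_ids) < 2 or len(post_ids) < 2:
        raise ValueError(
            f"each phase needs >=2 samples, got pre={len(pre_ids)}, post={len(post_ids)}"
        )
    results = []
    for gene in matrix.target_genes:
        pre = matrix.values.loc[pre_ids, gene].to_numpy()
        post = matrix.values.loc[post_ids, gene].to_numpy()
        t, p, _df, _ = pooled_t(post, pre)
        results.append(
            GroupTestResult(
                gene=gene,
                group_sizes=(len(pre_ids), len(post_ids)),
                t=t,
                p=p,
                significant=p < alpha,
                direction=int(np.sign(post.mean() - pre.mean())),
            )
        )
    return results, [r for r in results if r.significant]


def concordance(
    fc_a: Mapping[str, float] | pd.Series, fc_b: Mapping[str, float] | pd.Series
) -> ConcordanceResult:
    """Pearson correlation between two per-gene log2 fold-change vectors.

    Genes are matched by name; at least three shared genes are required.
    The p-value comes from the t transform ``t = r*sqrt((n-2)/(1-r^2))``.
    """
    a = pd.Series(fc_a, dtype=float)
    b = pd.Series(fc_b, dtype=float)
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(f"need >=3 shared genes, got {len(shared)}")
    x = a.loc[shared].to_numpy()
    y = b.loc[shared].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance fold-change vector")
    n = len(shared)
    xc, yc = x - x.mean(), y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = t_sf_two_sided(float(t), n - 2)
    return ConcordanceResult(n=n, r=r, r_squared=r * r, p=p)


def load_crossplatform_fold_changes() -> pd.DataFrame:
    """Packaged day3-vs-day10 log2 fold changes for the 12 profiled genes.

    Columns: ``illumina_log2fc`` (RNA-seq), ``qpcr_log2fc``, ``range_fc``
    (untransformed min-to-max qPCR fold change over the stage); indexed by
    gene name.  The RNA-seq column is consumed as given data, never
    recomputed.
    """
    with resources.files("moltmark.data").joinpath(_FIXTURE).open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    return df.set_index("gene")
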