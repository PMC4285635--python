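"""PCA of the normalized expression matrix and contiguous periodization.

The normalized samples x genes matrix is mean-centered per gene (no
variance scaling: all genes share the log2 scale, and loadings should
reflect magnitude) and decomposed by eigendecomposition of the sample
covariance.  Daily mean scores on the first two components are then
segmented into contiguous early/middle/late periods by exhaustive search
over all two-breakpoint partitions, minimizing the within-segment sum of
squared distances to segment centroids — a deterministic, seed-free
replacement for eyeballing score clusters, which respects temporal order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = ["PeriodModel", "run_pca", "daily_scores", "segment_days"]

PERIOD_NAMES = ("early", "middle", "late")


@dataclass
class PeriodModel:
    """Fitted PCA plus (optionally) the periodization of daily scores."""

    eigenvectors: pd.DataFrame  # genes x PCs, unit-norm columns
    variance_fractions: np.ndarray  # all components, sums to 1
    gene_means: pd.Series  # centering vector
    scores: pd.DataFrame  # samples x PCs
    daily_scores: pd.DataFrame | None = None  # day groups x (PC1, PC2)
    breakpoints: tuple[int, int] | None = None
    period_labels: dict[float, str] = field(default_factory=dict)


def run_pca(matrix: ExpressionMatrix, k: int = 5) -> PeriodModel:
    """Centered (unscaled) PCA keeping the first ``k`` components.

    Deterministic sign convention: each eigenvector is flipped so that its
    largest-magnitude gene loading is positive.  ``variance_fractions``
    covers all components so that it sums to exactly 1.
    """
    if not matrix.normalized:
        raise ValueError("PCA expects the normalized expression matrix")
    X = matrix.values.to_numpy(dtype=float)
    n, p = X.shape
    max_k = min(n, p)
    if not 1 <= k <= max_k:
        raise ValueError(f"k must be in [1, {max_k}], got {k}")
    means = X.mean(axis=0)
    Xc = X - means
    cov = (Xc.T @ Xc) / (n - 1)
    eigval, eigvec = np.linalg.eigh(cov)  # ascending
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # fix signs: largest-|loading| entry positive
    for j in range(eigvec.shape[1]):
        i = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    total = eigval.sum()
    fractions = eigval / total if total > 0 else np.zeros_like(eigval)
    pcs = [f"PC{j + 1}" for j in range(k)]
    vectors = pd.DataFrame(eigvec[:, :k], index=matrix.values.columns, columns=pcs)
    scores = pd.DataFrame(Xc @ eigvec[:, :k], index=matrix.values.index, columns=pcs)
    return PeriodModel(
        eigenvectors=vectors,
        variance_fractions=fractions,
        gene_means=pd.Series(means, index=matrix.values.columns),
        scores=scores,
    )


def daily_scores(model: PeriodModel, matrix: ExpressionMatrix) -> pd.DataFrame:
    """Mean (PC1, PC2) score per day group, ordered by day."""
    if model.scores.shape[1] < 2:
        raise ValueError("need at least 2 components for daily scores")
    df = model.scores[["PC1", "PC2"]].copy()
    df["day_group"] = matrix.day_groups
    out = df.groupby("day_group", sort=True).mean()
    model.daily_scores = out
    return out


def _partition_cost(points: np.ndarray, bounds: Sequence[int]) -> float:
    cost = 0.0
    for lo, hi in itertools.pairwise(bounds):
        seg = points[lo:hi]
        cost += float(((seg - seg.mean(axis=0)) ** 2).sum())
    return cost


def segment_days(
    scores: pd.DataFrame, n_segments: int = 3
) -> tuple[tuple[int, ...], dict[float, str]]:
    """Optimal contiguous segmentation of ordered daily scores.

    Exhaustively evaluates every contiguous partition of the day groups into
    ``n_segments`` non-empty runs and returns the breakpoints (indices where
    a new segment starts) with the smallest total within-segment sum of
    squared Euclidean distances to segment centroids.  Ties break toward the
    earliest breakpoints.  Labels are positional: the first segment is
    always ``early``, then ``middle``, then ``late`` (and ``period4``, ...
    beyond three).
    """
    D = len(scores)
    if D < n_segments:
        raise ValueError(f"need >= {n_segments} day groups, got {D}")
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    pts = scores.to_numpy(dtype=float)
    best: tuple[float, tuple[int, ...]] | None = None
    for cuts in itertools.combinations(range(1, D), n_segments - 1):
        cost = _partition_cost(pts, (0, *cuts, D))
        if best is None or cost < best[0] - 1e-12:
            best = (cost, cuts)
    assert best is not None
    cuts = best[1]
    names = list(PERIOD_NAMES[:n_segments]) + [
        f"period{i + 1}" for i in range(len(PERIOD_NAMES), n_segments)
    ]
    labels: dict[float, str] = {}
    bounds = (0, *cuts, D)
    for seg_idx, (lo, hi) in enumerate(itertools.pairwise(bounds)):
        for day in scores.index[lo:hi]:
            labels[float(day)] = names[seg_idx]
    return cuts, labels


def periodize(model: PeriodModel, matrix: ExpressionMatrix, n_segments: int = 3) -> PeriodModel:
    """Convenience: daily scores + segmentation, stored on the model."""
    ds = daily_scores(model, matrix)
    cuts, labels = segment_days(ds, n_segments)
    model.breakpoints = cuts if len(cuts) != 2 else (cuts[0], cuts[1])
    model.period_labels = labels
    return model
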