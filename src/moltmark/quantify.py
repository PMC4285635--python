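"""Relative qPCR quantification and housekeeping normalization.

Raw Cq values are converted to relative transcript quantities through a
per-gene standard curve fit to a plasmid dilution series
(``Cq = intercept + slope * log10(quantity)``), log2-transformed, and then
normalized by subtracting the per-sample log2 geometric mean of a set of
stably expressed reference genes.

Quantities are relative (plasmid copy scale); no inter-plate calibrator is
applied.  Duplicate wells are averaged on the Cq scale before
back-transformation; a duplicate spread above 1 cycle is recorded as a QC
warning but is not fatal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = [
    "WellRecord",
    "StandardCurve",
    "QPCRQualityWarning",
    "fit_standard_curve",
    "quantify",
    "normalization_factor",
    "normalize",
    "read_cq_tsv",
    "read_standards_tsv",
]

#: duplicate-well Cq spread (cycles) above which a QC warning is emitted
DUPLICATE_SPREAD_WARN = 1.0


class QPCRQualityWarning(UserWarning):
    """Non-fatal quality problem in qPCR input (e.g. discordant duplicates)."""


@dataclass(frozen=True)
class WellRecord:
    """Cq readings of one sample x gene reaction (duplicate wells)."""

    sample_id: str
    gene: str
    cq_values: tuple[float, ...]
    day: float = float("nan")
    replicate: int = 0
    molt_phase: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "cq_values", tuple(float(c) for c in self.cq_values))
        if not 1 <= len(self.cq_values) <= 4:
            raise ValueError("expected 1-4 Cq values per well group")
        if any(not (0 < c < 45) for c in self.cq_values):
            raise ValueError(f"Cq out of range (0, 45): {self.cq_values}")


@dataclass(frozen=True)
class StandardCurve:
    """Linear fit of Cq against log10 template quantity for one gene.

    ``efficiency`` is the per-cycle amplification gain minus one:
    ``10 ** (-1 / slope) - 1``; a perfect doubling gives slope -3.3219 and
    efficiency 1.0.
    """

    gene: str
    intercept: float
    slope: float
    efficiency: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError(f"inverted curve for {self.gene!r}: slope must be negative")

    def quantity(self, cq: float) -> float:
        """Relative quantity for a measured Cq (inverse of the fitted line)."""
        return 10.0 ** ((cq - self.intercept) / self.slope)


def fit_standard_curve(
    gene: str, dilutions: Sequence[tuple[float, float]]
) -> StandardCurve:
    """Ordinary least-squares standard curve from (log10 quantity, mean Cq) points.

    Requires at least three dilution points with non-zero quantity spread.
    """
    if len(dilutions) < 3:
        raise ValueError(f"need >=3 dilution points for {gene!r}, got {len(dilutions)}")
    log_q = np.asarray([d[0] for d in dilutions], dtype=float)
    cq = np.asarray([d[1] for d in dilutions], dtype=float)
    if np.ptp(log_q) == 0:
        raise ValueError(f"zero quantity spread in standards for {gene!r}")
    slope, intercept = np.polyfit(log_q, cq, 1)
    if slope >= 0:
        raise ValueError(f"inverted curve for {gene!r}: fitted slope {slope:.3g} >= 0")
    resid = cq - (intercept + slope * log_q)
    ss_tot = float(np.sum((cq - cq.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    efficiency = 10.0 ** (-1.0 / slope) - 1.0
    if not 0 < efficiency <= 1.2:
        warnings.warn(
            f"amplification efficiency {efficiency:.2f} for {gene!r} outside (0, 1.2]",
            QPCRQualityWarning,
            stacklevel=2,
        )
    return StandardCurve(
        gene=gene,
        intercept=float(intercept),
        slope=float(slope),
        efficiency=float(efficiency),
        r_squared=float(r_squared),
    )


def quantify(
    wells: Iterable[WellRecord],
    curves: Mapping[str, StandardCurve],
    housekeeping_genes: Sequence[str] = (),
) -> ExpressionMatrix:
    """Convert well records to an un-normalized log2 expression matrix.

    Duplicate Cq values are averaged per well group; the mean Cq is mapped
    through the gene's standard curve and the relative quantity is stored as
    its log2.
    """
    records = []
    for w in wells:
        if w.gene not in curves:
            raise KeyError(f"no standard curve for gene {w.gene!r}")
        spread = max(w.cq_values) - min(w.cq_values)
        if spread > DUPLICATE_SPREAD_WARN:
            warnings.warn(
                f"duplicate Cq spread {spread:.2f} > {DUPLICATE_SPREAD_WARN} cycles "
                f"for sample {w.sample_id!r}, gene {w.gene!r}",
                QPCRQualityWarning,
                stacklevel=2,
            )
        mean_cq = float(np.mean(w.cq_values))
        value = float(np.log2(curves[w.gene].quantity(mean_cq)))
        records.append(
            (w.sample_id, w.day, w.replicate, w.molt_phase, w.gene, value)
        )
    if not records:
        raise ValueError("no well records supplied")
    long = pd.DataFrame(
        records,
        columns=["sample_id", "day", "replicate", "molt_phase", "gene", "log2_value"],
    )
    return ExpressionMatrix.from_long(
        long, normalized=False, housekeeping_genes=tuple(housekeeping_genes)
    )


def normalization_factor(
    sample_id: str, matrix: ExpressionMatrix, hk: Sequence[str] | None = None
) -> float:
    """Per-sample normalization factor in log2 units.

    The arithmetic mean of the sample's log2 housekeeping values, which
    equals the log2 of the geometric mean of their linear-scale quantities.
    """
    hk = list(matrix.housekeeping_genes if hk is None else hk)
    if not hk:
        raise ValueError("empty housekeeping gene list")
    missing = set(hk) - set(matrix.values.columns)
    if missing:
        raise KeyError(f"housekeeping genes absent from matrix: {sorted(missing)}")
    return float(matrix.values.loc[sample_id, hk].mean())


def normalize(matrix: ExpressionMatrix, hk: Sequence[str] | None = None) -> ExpressionMatrix:
    """Subtract each sample's housekeeping geometric-mean factor.

    Returns a normalized matrix with the reference-gene columns dropped.
    A value of 0 means expression equal to the geometric mean of the
    housekeeping genes; negative values mean lower expression.
    """
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    hk = list(matrix.housekeeping_genes if hk is None else hk)
    if not hk:
        raise ValueError("empty housekeeping gene list")
    missing = set(hk) - set(matrix.values.columns)
    if missing:
        raise KeyError(f"housekeeping genes absent from matrix: {sorted(missing)}")
    nf = matrix.values[hk].mean(axis=1)
    targets = [g for g in matrix.values.columns if g not in set(hk)]
    values = matrix.values[targets].sub(nf, axis=0)
    return ExpressionMatrix(
        values=values,
        samples=matrix.samples.copy(),
        normalized=True,
        housekeeping_genes=tuple(hk),
    )


# ---------------------------------------------------------------------- #
# TSV readers for raw inputs


def read_cq_tsv(path: str | Path) -> list[WellRecord]:
    """Read a raw Cq table: sample_id, gene, cq [, day, replicate, molt_phase].

    One row per well; wells of the same (sample, gene) are grouped into a
    single :class:`WellRecord`.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    needed = {"sample_id", "gene", "cq"}
    if not needed <= set(df.columns):
        raise ValueError(f"Cq table must have columns {sorted(needed)}")
    records = []
    for (sid, gene), grp in df.groupby(["sample_id", "gene"], sort=False):
        first = grp.iloc[0]
        records.append(
            WellRecord(
                sample_id=str(sid),
                gene=str(gene),
                cq_values=tuple(grp["cq"].astype(float)),
                day=float(first["day"]) if "day" in grp else float("nan"),
                replicate=int(first["replicate"]) if "replicate" in grp else 0,
                molt_phase=(
                    None
                    if "molt_phase" not in grp or pd.isna(first["molt_phase"])
                    else str(first["molt_phase"])
                ),
            )
        )
    return records


def read_standards_tsv(path: str | Path) -> dict[str, StandardCurve]:
    """Read a dilution-series table (gene, log10_quantity, cq) and fit curves."""
    df = pd.read_csv(path, sep="\t")
    needed = {"gene", "log10_quantity", "cq"}
    if not needed <= set(df.columns):
        raise ValueError(f"standards table must have columns {sorted(needed)}")
    curves = {}
    for gene, grp in df.groupby("gene", sort=False):
        pts = list(zip(grp["log10_quantity"].astype(float), grp["cq"].astype(float)))
        curves[str(gene)] = fit_standard_curve(str(gene), pts)
    return curves
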