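"""Core expression container and its TSV dialect.

The central object is :class:`ExpressionMatrix`: a samples-by-genes table of
log2 relative transcript quantities plus per-sample metadata (day since the
penultimate molt, replicate index, optional pre/post-apolysis label).  The
matrix exists in two states:

* **un-normalized** — raw relative quantities straight off the standard
  curves; housekeeping genes are still columns.
* **normalized** — each target-gene value has had the sample's normalization
  factor (log2 geometric mean of the housekeeping genes) subtracted, and the
  housekeeping columns are dropped.

On-disk representation is a long-format TSV with columns
``sample_id  day  replicate  gene  log2_value  molt_phase`` (UTF-8, header
row, '.' decimal, ``NA`` for missing molt phase).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "read_expression_tsv", "write_expression_tsv"]

#: long-format column order used by every reader/writer in the package
LONG_COLUMNS = ["sample_id", "day", "replicate", "gene", "log2_value", "molt_phase"]

_PHASES = {"pre", "post"}


@dataclass
class ExpressionMatrix:
    """Samples x genes log2 expression with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by sample_id with one column per gene; entries are
        log2 relative quantities.  No missing values are allowed.
    samples
        DataFrame indexed by sample_id with columns ``day`` (float),
        ``replicate`` (int) and ``molt_phase`` (``"pre"``/``"post"``/NA).
        May additionally carry a ``day_group`` column after day grouping.
    normalized
        Whether housekeeping normalization has been applied.
    housekeeping_genes
        Names of the reference genes.  For an un-normalized matrix these are
        columns of ``values``; a normalized matrix records them but has
        dropped the columns.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    normalized: bool = False
    housekeeping_genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.housekeeping_genes = tuple(self.housekeeping_genes)
        if not self.values.index.equals(self.samples.index):
            raise ValueError("values and samples must share the same sample index")
        if self.values.isna().any().any():
            raise ValueError("expression values must not contain missing entries")
        if self.normalized:
            overlap = set(self.housekeeping_genes) & set(self.values.columns)
            if overlap:
                raise ValueError(
                    f"normalized matrix still contains housekeeping genes: {sorted(overlap)}"
                )
        phases = self.samples["molt_phase"].dropna()
        bad = set(phases.unique()) - _PHASES
        if bad:
            raise ValueError(f"unknown molt_phase labels: {sorted(bad)}")

    # ------------------------------------------------------------------ #

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def target_genes(self) -> list[str]:
        """Genes that are not housekeeping references."""
        hk = set(self.housekeeping_genes)
        return [g for g in self.values.columns if g not in hk]

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def day_groups(self) -> pd.Series:
        """Day-group label per sample (falls back to raw day before grouping)."""
        if "day_group" in self.samples.columns:
            return self.samples["day_group"]
        return self.samples["day"]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return replace(
            self, values=self.values.loc[ids].copy(), samples=self.samples.loc[ids].copy()
        )

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        missing = set(genes) - set(self.values.columns)
        if missing:
            raise KeyError(f"genes not in matrix: {sorted(missing)}")
        hk = tuple(g for g in self.housekeeping_genes if g in genes)
        return replace(self, values=self.values[genes].copy(), housekeeping_genes=hk)

    # ------------------------------------------------------------------ #

    def to_long(self) -> pd.DataFrame:
        """Melt to the long-format table used on disk."""
        long = (
            self.values.rename_axis("sample_id")
            .reset_index()
            .melt(id_vars="sample_id", var_name="gene", value_name="log2_value")
        )
        meta = self.samples.rename_axis("sample_id").reset_index()
        long = long.merge(meta[["sample_id", "day", "replicate", "molt_phase"]], on="sample_id")
        return long[LONG_COLUMNS]

    @classmethod
    def from_long(
        cls,
        long: pd.DataFrame,
        *,
        normalized: bool = False,
        housekeeping_genes: Sequence[str] = (),
    ) -> "ExpressionMatrix":
        missing = set(LONG_COLUMNS[:5]) - set(long.columns)
        if missing:
            raise ValueError(f"long table missing columns: {sorted(missing)}")
        wide = long.pivot_table(
            index="sample_id", columns="gene", values="log2_value", sort=False
        )
        wide.columns.name = None
        meta_cols = ["day", "replicate"] + (["molt_phase"] if "molt_phase" in long else [])
        meta = long.drop_duplicates("sample_id").set_index("sample_id")[meta_cols]
        if "molt_phase" not in meta:
            meta["molt_phase"] = pd.NA
        order = meta.index
        return cls(
            values=wide.loc[order],
            samples=meta,
            normalized=normalized,
            housekeeping_genes=tuple(housekeeping_genes),
        )


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    long = matrix.to_long()
    long["molt_phase"] = long["molt_phase"].fillna("NA")
    long.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_expression_tsv(
    path: str | Path,
    *,
    normalized: bool = False,
    housekeeping_genes: Sequence[str] = (),
) -> ExpressionMatrix:
    long = pd.read_csv(
        path, sep="\t", na_values=["NA"], keep_default_na=False,
        dtype={"sample_id": str, "gene": str},
    )
    return ExpressionMatrix.from_long(
        long, normalized=normalized, housekeeping_genes=housekeeping_genes
    )
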