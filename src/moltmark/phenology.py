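"""Cohort-level developmental bookkeeping.

Counts and percentages over individually staged animals: stage composition
per sampling day, molt-phase (pre/post-apolysis) classification from the
mandibular jaw phase, gonad differentiation and sex ratios, median stage
duration from completed molt-to-molt intervals, and oil-sac volume
summaries.  Denominators exclude missing observations per metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortRecord",
    "PRE_APOLYSIS_PHASES",
    "POST_APOLYSIS_PHASES",
    "classify_apolysis",
    "proportion",
    "median_stage_duration",
    "daily_composition",
    "read_cohort_tsv",
]

logger = logging.getLogger(__name__)

#: jaw phases before cuticle separation, in developmental order
PRE_APOLYSIS_PHASES = ("post-molt", "late post-molt", "interphase", "columnar-cell")
#: jaw phases at or after cuticle separation
POST_APOLYSIS_PHASES = ("apolysis", "tooth-molds", "silicified-teeth", "extricated-teeth")

STAGES = ("C4", "C5", "adult")
GONAD_STATES = ("none", "rudimentary", "developing", "differentiated")


@dataclass(frozen=True)
class CohortRecord:
    """One staged individual."""

    individual_id: str
    sample_day: float
    stage: str
    jaw_phase: str | None = None
    gonad_state: str | None = None
    sex: str | None = None
    oil_sac_volume: float | None = None  # mm^3
    molt_day: float | None = None  # day of the C4->C5 molt
    adult_day: float | None = None  # day of the terminal molt, if observed

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.gonad_state is not None and self.gonad_state not in GONAD_STATES:
            raise ValueError(f"unknown gonad state {self.gonad_state!r}")
        if self.sex is not None and self.gonad_state != "differentiated":
            raise ValueError("sex can only be recorded for differentiated gonads")
        if self.oil_sac_volume is not None and self.oil_sac_volume < 0:
            raise ValueError("oil_sac_volume must be >= 0")


def classify_apolysis(jaw_phase: str | None) -> str:
    """Map a jaw phase to ``pre`` or ``post`` apolysis."""
    if jaw_phase is None:
        raise ValueError("unstaged: jaw phase is missing")
    if jaw_phase in PRE_APOLYSIS_PHASES:
        return "pre"
    if jaw_phase in POST_APOLYSIS_PHASES:
        return "post"
    raise ValueError(f"unknown jaw phase {jaw_phase!r}")


def proportion(count: int, total: int) -> float:
    """Percentage 100*count/total, rounded to one decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must be within [0, total]")
    return round(100.0 * count / total, 1)


def median_stage_duration(records: Iterable[CohortRecord]) -> float:
    """Median completed C5 stage duration in days.

    Uses individuals with both molt days observed; an even count takes the
    midpoint of the central pair.  Interval censoring of animals that never
    molted is ignored (they simply do not contribute).
    """
    durations = [
        r.adult_day - r.molt_day
        for r in records
        if r.adult_day is not None and r.molt_day is not None
    ]
    if not durations:
        raise ValueError("no completed molt-to-molt intervals")
    return float(np.median(durations))


def daily_composition(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """Per-day stage, molt-phase and gonad percentages plus oil-sac stats.

    Percentages use per-metric non-missing denominators.  Days with no
    records are omitted (with a log notice if the day range has gaps);
    oil-sac columns are NaN on days where every volume is missing.
    """
    if not records:
        raise ValueError("no cohort records")
    df = pd.DataFrame(
        {
            "day": [r.sample_day for r in records],
            "stage": [r.stage for r in records],
            "jaw_phase": [r.jaw_phase for r in records],
            "gonad": [r.gonad_state for r in records],
            "volume": [r.oil_sac_volume for r in records],
        }
    )
    rows = []
    for day, grp in df.groupby("day", sort=True):
        row: dict[str, float] = {"day": float(day), "n": len(grp)}
        for stage in STAGES:
            row[f"pct_{stage}"] = proportion(int((grp["stage"] == stage).sum()), len(grp))
        staged = grp["jaw_phase"].dropna()
        if len(staged):
            post = sum(classify_apolysis(ph) == "post" for ph in staged)
            row["pct_post_apolysis"] = proportion(post, len(staged))
        gonads = grp["gonad"].dropna()
        if len(gonads):
            row["pct_differentiated"] = proportion(
                int((gonads == "differentiated").sum()), len(gonads)
            )
        vols = grp["volume"].dropna()
        if len(vols):
            row["oil_sac_mean"] = float(vols.mean())
            row["oil_sac_sd"] = float(vols.std(ddof=1)) if len(vols) > 1 else 0.0
        rows.append(row)
    out = pd.DataFrame(rows).set_index("day")
    observed = set(out.index)
    full = {float(d) for d in range(int(min(observed)), int(max(observed)) + 1)}
    missing = sorted(full - observed)
    if missing:
        logger.info("no cohort records on days %s; omitted", missing)
    return out


def read_cohort_tsv(path: str | Path) -> list[CohortRecord]:
    """Read a cohort table with the fields of :class:`CohortRecord`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)

    def opt(row, col, cast=str):
        if col not in df.columns or pd.isna(row[col]):
            return None
        return cast(row[col])

    return [
        CohortRecord(
            individual_id=str(row["individual_id"]),
            sample_day=float(row["sample_day"]),
            stage=str(row["stage"]),
            jaw_phase=opt(row, "jaw_phase"),
            gonad_state=opt(row, "gonad_state"),
            sex=opt(row, "sex"),
            oil_sac_volume=opt(row, "oil_sac_volume", float),
            molt_day=opt(row, "molt_day", float),
            adult_day=opt(row, "adult_day", float),
        )
        for _, row in df.iterrows()
    ]
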