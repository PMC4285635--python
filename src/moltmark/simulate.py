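"""Synthetic copepod-cohort expression generator.

Emulates a within-stage molt-cycle profiling study: a cohort of C5
copepodids of known age since the penultimate molt is sampled destructively
each day, pools of whole animals are homogenized, and log2 relative
expression of 12 dynamically regulated target genes plus 4 stable
housekeeping genes is measured in each pool.

Each gene follows one of seven trend archetypes (smooth deterministic
trajectories on the log2 scale); individual animals add lognormal biological
noise, and genes whose expression tracks molt-cycle progress rather than
calendar age (``phase_locked``) are evaluated at an effective day shifted by
the individual's apolysis timing.  The generator returns both the pooled
expression matrix and the ground truth needed for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = [
    "GeneProfile",
    "CohortDesign",
    "CohortTruth",
    "trend_value",
    "simulate_cohort",
    "simulate_phase_pools",
    "default_paper_profiles",
    "DEFAULT_HOUSEKEEPING",
    "PLANTED_PAIR",
]

ARCHETYPES = frozenset(
    {"decreasing", "increasing", "surge", "u_shaped", "inverted_u", "spike_then_rise", "flat"}
)

#: default reference genes: moderate, stable expression
DEFAULT_HOUSEKEEPING = ("TSG", "UBX", "SNP", "EF1a")

#: gene pair the default profiles plant as the best early/late discriminator
PLANTED_PAIR = ("Torso-like", "HR38b")

# pre-surge decline of the `surge` archetype: a Gaussian-shaped descent into
# a trough (no recovery; the steep rise takes over from the trough level).
# Depth 2.5 log2 units (~6x decline), trough 2 days before the surge center,
# descent sd 1.4 days - mirroring the early co-decline with the
# mid-cycle-minimum genes that stabilizes their expression ratio
_SURGE_DIP = 2.5
_SURGE_TROUGH_LEAD = 2.0
_SURGE_TROUGH_SD = 1.4
# transient spike of `spike_then_rise`: day of peak, Gaussian sd (days), and
# height as a fraction of the profile amplitude
_SPIKE_DAY = 6.0
_SPIKE_SD = 0.6
_SPIKE_FRACTION = 0.6


@dataclass(frozen=True)
class GeneProfile:
    """Deterministic trend + noise model for one gene.

    ``width`` sets transition steepness: for ramp archetypes it is the span
    of days over which ~76% of the logistic transition occurs; for bump
    archetypes it is the Gaussian standard deviation in days.
    ``phase_locked`` genes are driven by time-to-apolysis rather than
    calendar day, so between-animal asynchrony in molt progression inflates
    their replicate variance.
    """

    gene: str
    archetype: str
    baseline: float = 0.0
    amplitude: float = 0.0
    breakpoint_day: float = 7.0
    width: float = 2.5
    noise_sd: float = 0.5
    phase_locked: bool = False

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r} for gene {self.gene!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if not math.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")


@dataclass(frozen=True)
class CohortDesign:
    """Sampling design of the synthetic cohort.

    Days 11-12 and 13-14 of the study design yield pooled replicates that
    the analysis combines; they are represented directly as pseudo-days 11.5
    and 13.5 so the default design produces the 36 analyzed samples
    (10 days x 3 replicates + 2 combined groups x 3 replicates).
    """

    days: tuple[float, ...] = tuple(float(d) for d in range(1, 11)) + (11.5, 13.5)
    replicates_per_day: int = 3
    copepods_per_pool: int = 3
    housekeeping_genes: tuple[str, ...] = DEFAULT_HOUSEKEEPING
    apolysis_day_mean: float = 8.0
    apolysis_day_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.days) == 0:
            raise ValueError("design needs at least one sampling day")
        if self.replicates_per_day < 1 or self.copepods_per_pool < 1:
            raise ValueError("replicates_per_day and copepods_per_pool must be >= 1")
        if len(self.housekeeping_genes) < 2:
            raise ValueError("need at least 2 housekeeping genes")
        if self.apolysis_day_sd < 0:
            raise ValueError("apolysis_day_sd must be >= 0")


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort, for recovery tests."""

    profiles: dict[str, GeneProfile]
    planted_pair: tuple[str, str]
    apolysis_days: dict[str, float] = field(default_factory=dict)
    pool_membership: dict[str, tuple[str, ...]] = field(default_factory=dict)


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _step(t, center: float, width: float):
    """Logistic 0->1 step; ~76% of the rise occurs within `width` days of center."""
    return _logistic(4.0 * (np.asarray(t, dtype=float) - center) / width)


def _bump(t, center: float, sd: float):
    x = (np.asarray(t, dtype=float) - center) / sd
    return np.exp(-0.5 * x * x)


def trend_value(profile: GeneProfile, t) -> np.ndarray | float:
    """Expected log2 expression of ``profile`` at effective day(s) ``t``.

    Deterministic and smooth in ``t``; vectorized over array input.
    """
    t = np.asarray(t, dtype=float)
    b, w, amp = profile.breakpoint_day, profile.width, profile.amplitude
    base = profile.baseline
    if profile.archetype == "flat":
        out = np.full_like(t, base)
    elif profile.archetype == "increasing":
        out = base + amp * _step(t, b, w)
    elif profile.archetype == "decreasing":
        out = base - amp * _step(t, b, w)
    elif profile.archetype == "surge":
        # Gaussian-shaped descent into a trough just before the surge, then a
        # steep logistic rise of the full amplitude from the trough level
        trough = b - _SURGE_TROUGH_LEAD
        out = (
            base
            - _SURGE_DIP * _bump(np.minimum(t, trough), trough, _SURGE_TROUGH_SD)
            + amp * _step(t, b, w)
        )
    elif profile.archetype == "u_shaped":
        out = base - amp * _bump(t, b, w)
    elif profile.archetype == "inverted_u":
        out = base + amp * _bump(t, b, w)
    elif profile.archetype == "spike_then_rise":
        out = (
            base
            + _SPIKE_FRACTION * amp * _bump(t, _SPIKE_DAY, _SPIKE_SD)
            + amp * _step(t, b, w)
        )
    else:  # pragma: no cover - guarded by GeneProfile validation
        raise ValueError(f"unknown archetype {profile.archetype!r}")
    return float(out) if out.ndim == 0 else out


def simulate_cohort(
    design: CohortDesign,
    profiles: Mapping[str, GeneProfile],
    seed: int | None = None,
) -> tuple[ExpressionMatrix, CohortTruth]:
    """Simulate one cohort; returns an un-normalized matrix plus ground truth.

    Per sampled pool, ``copepods_per_pool`` fresh individuals are drawn (the
    sampling is destructive, so individuals never recur across days).  Each
    individual i gets an apolysis day ~ Normal(mean, sd) truncated at 0; for
    phase-locked genes its expression is evaluated at
    ``day - (apolysis_day_i - apolysis_day_mean)``.  Individual log2 values
    get additive Gaussian noise, pools average on the linear scale
    (homogenized tissue mixes RNA mass linearly), and the pool's molt-phase
    label is ``post`` when the majority of its members have undergone
    apolysis by the sampling day.
    """
    if not profiles:
        raise ValueError("profiles must not be empty")
    missing_hk = set(design.housekeeping_genes) - set(profiles)
    if missing_hk:
        raise ValueError(f"profiles missing housekeeping genes: {sorted(missing_hk)}")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    genes = list(profiles)
    majority = design.copepods_per_pool // 2 + 1

    rows: dict[str, list] = {g: [] for g in genes}
    meta_rows = []
    apolysis_days: dict[str, float] = {}
    pool_membership: dict[str, tuple[str, ...]] = {}

    for day in design.days:
        for rep in range(1, design.replicates_per_day + 1):
            sample_id = f"d{day:g}_r{rep}"
            members = tuple(
                f"{sample_id}_c{i + 1}" for i in range(design.copepods_per_pool)
            )
            apol = design.apolysis_day_mean + design.apolysis_day_sd * rng.standard_normal(
                design.copepods_per_pool
            )
            apol = np.maximum(apol, 0.0)
            for ind, a in zip(members, apol):
                apolysis_days[ind] = float(a)
            pool_membership[sample_id] = members
            n_post = int(np.sum(apol <= day))
            phase = "post" if n_post >= majority else "pre"
            for g in genes:
                prof = profiles[g]
                if prof.phase_locked:
                    t_eff = day - (apol - design.apolysis_day_mean)
                else:
                    t_eff = np.full(design.copepods_per_pool, float(day))
                log2_ind = trend_value(prof, t_eff)
                log2_ind = np.atleast_1d(log2_ind) + prof.noise_sd * rng.standard_normal(
                    design.copepods_per_pool
                )
                pooled = math.log2(np.mean(np.exp2(log2_ind)))
                rows[g].append(pooled)
            meta_rows.append((sample_id, float(day), rep, phase))

    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "day", "replicate", "molt_phase"]
    ).set_index("sample_id")
    values = pd.DataFrame(rows, index=meta.index)
    matrix = ExpressionMatrix(
        values=values,
        samples=meta,
        normalized=False,
        housekeeping_genes=tuple(design.housekeeping_genes),
    )
    truth = CohortTruth(
        profiles=dict(profiles),
        planted_pair=PLANTED_PAIR if all(g in profiles for g in PLANTED_PAIR) else ("", ""),
        apolysis_days=apolysis_days,
        pool_membership=pool_membership,
    )
    return matrix, truth


def simulate_phase_pools(
    profiles: Mapping[str, GeneProfile],
    seed: int,
    n_pre: int = 3,
    n_post: int = 4,
    copepods_per_pool: int = 3,
    days: Sequence[float] = (8.0, 10.0),
    apolysis_day_mean: float = 8.0,
    apolysis_day_sd: float = 2.0,
    housekeeping_genes: Sequence[str] = DEFAULT_HOUSEKEEPING,
) -> ExpressionMatrix:
    """Simulate the known-molt-phase design: phase-pure pools.

    Mid-stage individuals are sampled on the given days, each is staged
    (post-apolysis iff its apolysis day is at or before its sampling day),
    and pools are assembled from animals of identical phase — the design
    used to contrast pre- vs post-apolysis expression directly, without the
    phase mixing that pooled calendar sampling produces.  Returns an
    un-normalized matrix whose ``molt_phase`` labels are exact.
    """
    if n_pre < 2 or n_post < 2:
        raise ValueError("need >=2 pools per phase for a contrast")
    rng = np.random.default_rng(seed)
    genes = list(profiles)
    rows: dict[str, list] = {g: [] for g in genes}
    meta_rows = []
    targets = [("pre", i) for i in range(1, n_pre + 1)] + [
        ("post", i) for i in range(1, n_post + 1)
    ]
    for phase, rep in targets:
        day = float(days[rng.integers(len(days))])
        # rejection-sample same-phase individuals for this pool
        apol: list[float] = []
        while len(apol) < copepods_per_pool:
            a = max(apolysis_day_mean + apolysis_day_sd * rng.standard_normal(), 0.0)
            if (a <= day) == (phase == "post"):
                apol.append(a)
        apol_arr = np.asarray(apol)
        for g in genes:
            prof = profiles[g]
            if prof.phase_locked:
                t_eff = day - (apol_arr - apolysis_day_mean)
            else:
                t_eff = np.full(copepods_per_pool, day)
            log2_ind = np.atleast_1d(trend_value(prof, t_eff))
            log2_ind = log2_ind + prof.noise_sd * rng.standard_normal(copepods_per_pool)
            rows[g].append(math.log2(np.mean(np.exp2(log2_ind))))
        meta_rows.append((f"{phase}_r{rep}", day, rep, phase))
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "day", "replicate", "molt_phase"]
    ).set_index("sample_id")
    return ExpressionMatrix(
        values=pd.DataFrame(rows, index=meta.index),
        samples=meta,
        normalized=False,
        housekeeping_genes=tuple(g for g in housekeeping_genes if g in profiles),
    )


def default_paper_profiles(noise_sd: float = 0.5) -> dict[str, GeneProfile]:
    """The 12 target-gene profiles of the default study, plus 4 references.

    Amplitudes are set so each gene's expected min-to-max untransformed fold
    change over the stage approximates its observed range fold change
    (e.g. ELOV 30x, FTZ-F1 32.0x, Torso-like 1024.2x).  Shapes follow the
    observed trajectories: the lipid genes FABP/ELOV decline steeply through
    the first two thirds of the stage, HR78/ERR/HR3/HR38a change steadily
    across the whole series, Vtg rises mostly after day 10, Torso-like
    declines into a trough around day 6 and then surges ~768-fold between
    days 7 and 10, FTZ-F1 and HR38b are U-shaped with mid-cycle minima, EcR
    shows a weak inverted-U, and Fem-1 is near-flat with a transient day-6
    spike before a late rise.

    Two features of the observed replicate structure are built in.  First,
    EcR and Fem-1 are phase-locked: their expression tracks molt-cycle
    progress rather than age within stage, so replicate scatter grows with
    developmental asynchrony.  Second, per-gene ``noise_sd`` is the base
    ``noise_sd`` argument times a gene-specific scatter multiplier that
    mirrors the widely differing replicate ribbons of the measured profiles
    (the lipid genes are by far the noisiest; Torso-like and the U-shaped
    receptors are tight).  Together with the parallel early declines of
    Torso-like and HR38b, this is what makes (Torso-like, HR38b) the planted
    best early/late discriminator ratio.
    """
    # replicate-scatter multipliers on the base noise level
    scatter = {
        "FABP": 3.5, "ELOV": 3.5, "HR78": 3.0, "ERR": 3.0,
        "HR3": 1.5, "HR38a": 1.5, "Vtg": 1.5,
        "Torso-like": 1.0, "FTZ-F1": 1.5, "HR38b": 1.0,
        "EcR": 1.5, "Fem-1": 1.5,
    }

    def p(gene, archetype, baseline, range_fc, breakpoint_day, width, **kw):
        return GeneProfile(
            gene=gene,
            archetype=archetype,
            baseline=baseline,
            amplitude=math.log2(range_fc),
            breakpoint_day=breakpoint_day,
            width=width,
            noise_sd=noise_sd * scatter[gene],
            **kw,
        )

    profiles = {
        "FABP": p("FABP", "decreasing", 8.0, 15.6, 6.0, 4.5),
        "ELOV": p("ELOV", "decreasing", 8.0, 30.0, 6.0, 4.0),
        "HR78": p("HR78", "decreasing", 6.0, 12.8, 7.0, 6.0),
        "ERR": p("ERR", "decreasing", 5.0, 5.3, 7.0, 6.0),
        "HR3": p("HR3", "increasing", 0.0, 64.2, 7.0, 6.0),
        "HR38a": p("HR38a", "increasing", 2.0, 5.9, 7.0, 6.0),
        "Vtg": p("Vtg", "increasing", -2.0, 597.9, 11.5, 3.0),
        "Torso-like": p("Torso-like", "surge", -2.0, 1024.2, 8.5, 0.5),
        "FTZ-F1": p("FTZ-F1", "u_shaped", 6.0, 32.0, 6.0, 1.4),
        "HR38b": p("HR38b", "u_shaped", 5.0, 7.8, 6.5, 1.4),
        "EcR": p("EcR", "inverted_u", 2.0, 3.4, 9.0, 2.5, phase_locked=True),
        "Fem-1": p("Fem-1", "spike_then_rise", 2.0, 7.6, 10.0, 3.0, phase_locked=True),
    }
    for hk in DEFAULT_HOUSEKEEPING:
        profiles[hk] = GeneProfile(
            gene=hk, archetype="flat", baseline=5.0, noise_sd=0.4 * noise_sd
        )
    return profiles
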