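"""End-to-end pipeline: simulate/ingest -> quantify -> normalize -> profile
-> periodize -> screen -> compare -> concord, with TSV/JSON outputs.

Every stage logs one line with row counts and elapsed time; a fixed seed
makes simulate-based runs byte-identical.  All outputs are UTF-8 TSV
(header row, '.' decimal, ``NA`` for missing) plus a machine-readable
``summary.json``.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import contrasts, periods, ratios, simulate, timeseries
from .quantify import normalize as _normalize, quantify as _quantify, read_cq_tsv, read_standards_tsv
from .matrix import ExpressionMatrix, read_expression_tsv, write_expression_tsv

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("moltmark.pipeline")


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    When ``cq_file``/``standards_file`` are given the pipeline ingests raw
    qPCR wells; otherwise it simulates a synthetic cohort with the default
    study profiles.
    """

    out_dir: str | Path = "moltmark_run"
    seed: int = 0
    expression_file: str | Path | None = None  # pre-quantified long TSV
    cq_file: str | Path | None = None
    standards_file: str | Path | None = None
    housekeeping_genes: tuple[str, ...] = simulate.DEFAULT_HOUSEKEEPING
    combine_days: tuple[tuple[float, ...], ...] = ((11, 12), (13, 14))
    exclude_days: tuple[float, ...] = (15, 16)
    early_period: tuple[float, ...] = (1, 2, 3, 4, 5)
    late_period: tuple[float, ...] = (10, 11.5, 13.5)
    alpha: float = 0.05
    k: int = 5
    n_segments: int = 3
    logfc_days: tuple[float, float] = (3.0, 10.0)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.housekeeping_genes:
            raise ValueError("housekeeping gene list must not be empty")
        if (self.cq_file is None) != (self.standards_file is None):
            raise ValueError("cq_file and standards_file must be given together")
        for f in (self.expression_file, self.cq_file, self.standards_file):
            if f is not None and not Path(f).exists():
                raise FileNotFoundError(f)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %-10s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the summary dict.

    Writes to ``config.out_dir``: the un-normalized and normalized matrices,
    daily summaries, fold changes, PCA loadings/scores/periods, the ranked
    ratio screen, molt-phase contrasts, concordance against the packaged
    cross-platform fold changes, and ``summary.json``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- acquire un-normalized matrix -------------------------------- #
    if config.cq_file is not None:
        curves = read_standards_tsv(config.standards_file)
        wells = read_cq_tsv(config.cq_file)
        matrix = _stage("quantify")(_quantify)(
            wells, curves, config.housekeeping_genes
        )
    elif config.expression_file is not None:
        matrix = _stage("ingest")(read_expression_tsv)(
            config.expression_file, housekeeping_genes=config.housekeeping_genes
        )
    else:
        design = simulate.CohortDesign(
            housekeeping_genes=tuple(config.housekeeping_genes), seed=config.seed
        )
        matrix, _truth = _stage("simulate")(simulate.simulate_cohort)(
            design, simulate.default_paper_profiles(), seed=config.seed
        )
    write_expression_tsv(matrix, out / "expression_unnormalized.tsv")

    # --- normalize ---------------------------------------------------- #
    norm = _stage("normalize")(_normalize)(matrix)
    write_expression_tsv(norm, out / "expression_normalized.tsv")

    # --- profile ------------------------------------------------------ #
    rules = timeseries.DayGroupingRules(
        combine=tuple(frozenset(s) for s in config.combine_days),
        exclude=frozenset(config.exclude_days),
    )
    grouped = _stage("profile")(timeseries.apply_grouping)(norm, rules)
    summary = timeseries.daily_summary(grouped)
    summary.to_csv(out / "daily_summary.tsv", sep="\t", index=False)
    day_a, day_b = config.logfc_days
    fc = pd.DataFrame(
        {
            "qpcr_log2fc": timeseries.logfc_between_days(grouped, day_a, day_b),
            "range_fc": timeseries.range_fc(grouped),
        }
    )
    fc.rename_axis("gene").to_csv(out / "fold_changes.tsv", sep="\t")

    # --- periodize ---------------------------------------------------- #
    model = _stage("periodize")(periods.run_pca)(grouped, k=config.k)
    model = periods.periodize(model, grouped, config.n_segments)
    model.eigenvectors.rename_axis("gene").to_csv(out / "pca_loadings.tsv", sep="\t")
    pd.DataFrame(
        {"variance_fraction": model.variance_fractions},
        index=[f"PC{i+1}" for i in range(len(model.variance_fractions))],
    ).rename_axis("component").to_csv(out / "pca_variance.tsv", sep="\t")
    ds = model.daily_scores.copy()
    ds["period"] = [model.period_labels[d] for d in ds.index]
    ds.rename_axis("day_group").to_csv(out / "daily_scores.tsv", sep="\t")

    # --- ratio screen (un-normalized; invariant anyway) --------------- #
    grouped_raw = timeseries.apply_grouping(matrix, rules)
    cfg = ratios.RatioScreenConfig(
        alpha=config.alpha,
        early_period=frozenset(config.early_period),
        late_period=frozenset(config.late_period),
    )
    results = _stage("screen")(ratios.screen)(grouped_raw, cfg)
    ratios.screen_table(results).to_csv(out / "ratio_screen.tsv", sep="\t")
    best = results[0]

    # --- molt-phase contrasts ----------------------------------------- #
    phase_counts = norm.samples["molt_phase"].value_counts()
    apolysis = None
    if phase_counts.get("pre", 0) >= 2 and phase_counts.get("post", 0) >= 2:
        all_res, sig = _stage("compare")(contrasts.apolysis_compare)(norm)
        pd.DataFrame([vars(r) for r in all_res]).to_csv(
            out / "apolysis_tests.tsv", sep="\t", index=False
        )
        apolysis = {
            "n_significant": len(sig),
            "significant_genes": [r.gene for r in sig],
        }

    # --- cross-platform concordance ----------------------------------- #
    fixture = contrasts.load_crossplatform_fold_changes()
    conc = _stage("concord")(contrasts.concordance)(
        fixture["illumina_log2fc"], fc["qpcr_log2fc"]
    )

    summary_json = {
        "seed": config.seed,
        "n_samples": int(matrix.n_samples),
        "n_target_genes": len(matrix.target_genes),
        "best_ratio": {
            "numerator": best.numerator_gene,
            "denominator": best.denominator_gene,
            "t": best.t,
            "p": best.p,
            "bonferroni_alpha": best.bonferroni_alpha,
            "mean_log2_ratio_early": best.mean_log2_ratio_early,
            "mean_log2_ratio_late": best.mean_log2_ratio_late,
        },
        "period_labels": {f"{k:g}": v for k, v in model.period_labels.items()},
        "variance_fractions_pc1_pc2": [
            float(model.variance_fractions[0]),
            float(model.variance_fractions[1]),
        ],
        "qpcr_log2fc": {g: float(v) for g, v in fc["qpcr_log2fc"].items()},
        "range_fc": {g: float(v) for g, v in fc["range_fc"].items()},
        "concordance_vs_rnaseq": {"n": conc.n, "r_squared": conc.r_squared, "p": conc.p},
        "apolysis": apolysis,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary_json, fh, indent=2, sort_keys=True)
    logger.info("run complete: %s", out / "summary.json")
    return summary_json
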