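"""Pairwise ratio screen: counting, orientation, invariances, recovery."""

import numpy as np
import pandas as pd
import pytest

from moltmark import (
    CohortDesign,
    DayGroupingRules,
    ExpressionMatrix,
    RatioScreenConfig,
    apply_grouping,
    bonferroni_alpha,
    default_paper_profiles,
    normalize,
    pair_count,
    sample_log_ratio,
    screen,
    simulate_cohort,
)
from moltmark.simulate import PLANTED_PAIR


class TestCounting:
    @pytest.mark.parametrize("n,expected", [(12, 66), (2, 1), (5, 10)])
    def test_pair_count(self, n, expected):
        assert pair_count(n) == expected

    def test_pair_count_matches_enumeration(self):
        from itertools import combinations

        for n in range(2, 10):
            assert pair_count(n) == len(list(combinations(range(n), 2)))

    def test_fewer_than_two_genes_rejected(self):
        with pytest.raises(ValueError):
            pair_count(1)

    @pytest.mark.parametrize(
        "alpha,m,expected", [(0.05, 66, 0.05 / 66), (0.05, 1, 0.05), (0.10, 4, 0.025)]
    )
    def test_bonferroni_cutoff(self, alpha, m, expected):
        assert bonferroni_alpha(alpha, m) == pytest.approx(expected, rel=1e-12)

    def test_bonferroni_rejects_zero_tests(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestSampleLogRatio:
    def test_difference_of_stored_log_values(self, tiny_matrix):
        assert sample_log_ratio(tiny_matrix, "s1", "A", "B") == pytest.approx(2.0)
        assert sample_log_ratio(tiny_matrix, "s1", "A", "A") == 0.0

    def test_missing_gene_rejected(self, tiny_matrix):
        with pytest.raises(KeyError):
            sample_log_ratio(tiny_matrix, "s1", "A", "nope")

    def test_identical_on_normalized_matrix(self, default_cohort):
        matrix, _ = default_cohort
        norm = normalize(matrix)
        for sid in list(matrix.values.index[:5]):
            raw = sample_log_ratio(matrix, sid, "Torso-like", "HR38b")
            nrm = sample_log_ratio(norm, sid, "Torso-like", "HR38b")
            assert nrm == pytest.approx(raw, abs=1e-12)


def _period_matrix(early_by_gene, late_by_gene):
    genes = list(early_by_gene)
    n_early = len(next(iter(early_by_gene.values())))
    n_late = len(next(iter(late_by_gene.values())))
    values = pd.DataFrame(
        {g: list(early_by_gene[g]) + list(late_by_gene[g]) for g in genes},
        index=[f"s{i}" for i in range(n_early + n_late)],
    )
    samples = pd.DataFrame(
        {
            "day": [1.0] * n_early + [10.0] * n_late,
            "replicate": 1,
            "molt_phase": pd.NA,
        },
        index=values.index,
    )
    return ExpressionMatrix(values=values, samples=samples)


class TestScreen:
    def test_hand_computed_pooled_t(self):
        # ratio A-B: early (1,2,3), late (4,5,6) -> t = 3*sqrt(3/2), df = 4
        m = _period_matrix(
            {"A": [1.0, 2.0, 3.0], "B": [0.0, 0.0, 0.0]},
            {"A": [4.0, 5.0, 6.0], "B": [0.0, 0.0, 0.0]},
        )
        cfg = RatioScreenConfig(early_period={1.0}, late_period={10.0})
        res = screen(m, cfg)
        assert len(res) == 1
        assert res[0].t == pytest.approx(3 * np.sqrt(1.5), rel=1e-12)
        assert res[0].p == pytest.approx(0.02131, abs=2e-4)

    def test_planted_perfect_separator_ranks_first(self):
        rng = np.random.default_rng(0)
        jitter = lambda n: rng.normal(scale=0.01, size=n)
        m = _period_matrix(
            {
                "A": -3 + jitter(6),
                "B": 3 + jitter(6),
                "C": rng.normal(scale=1.0, size=6),
            },
            {
                "A": 3 + jitter(4),
                "B": -3 + jitter(4),
                "C": rng.normal(scale=1.0, size=4),
            },
        )
        cfg = RatioScreenConfig(early_period={1.0}, late_period={10.0})
        res = screen(m, cfg)
        best = res[0]
        assert {best.numerator_gene, best.denominator_gene} == {"A", "B"}
        assert best.numerator_gene == "A"  # late-high gene in the numerator
        assert best.mean_log2_ratio_late > best.mean_log2_ratio_early

    def test_result_list_covers_all_pairs_with_permutation_ranks(self, default_cohort):
        matrix, _ = default_cohort
        grouped = apply_grouping(matrix, DayGroupingRules())
        res = screen(grouped)
        assert len(res) == pair_count(12)
        assert sorted(r.rank for r in res) == list(range(1, 67))
        assert all(r.bonferroni_alpha == pytest.approx(0.05 / 66) for r in res)
        # orientation invariant: all reported t >= 0, late mean >= early mean
        assert all(r.t >= 0 for r in res)
        assert all(r.mean_log2_ratio_late >= r.mean_log2_ratio_early for r in res)

    def test_normalization_invariance_of_t_values(self, default_cohort):
        matrix, _ = default_cohort
        rules = DayGroupingRules()
        raw = screen(apply_grouping(matrix, rules))
        nrm = screen(apply_grouping(normalize(matrix), rules))
        for a, b in zip(raw, nrm):
            assert (a.numerator_gene, a.denominator_gene) == (
                b.numerator_gene,
                b.denominator_gene,
            )
            assert abs(a.t - b.t) < 1e-12

    def test_housekeeping_genes_never_enter_pair_set(self, default_cohort):
        matrix, _ = default_cohort
        grouped = apply_grouping(matrix, DayGroupingRules())
        res = screen(grouped)
        hk = set(matrix.housekeeping_genes)
        assert all(
            r.numerator_gene not in hk and r.denominator_gene not in hk for r in res
        )

    def test_period_sample_counts_under_default_design(self, default_cohort):
        matrix, _ = default_cohort
        grouped = apply_grouping(matrix, DayGroupingRules())
        cfg = RatioScreenConfig()
        dg = grouped.day_groups
        assert int(dg.isin(cfg.early_period).sum()) == 15
        assert int(dg.isin(cfg.late_period).sum()) == 9

    def test_degenerate_zero_variance_pair_flagged(self):
        m = _period_matrix(
            {"A": [1.0, 1.0], "B": [0.0, 0.0]}, {"A": [2.0, 2.0], "B": [0.0, 0.0]}
        )
        cfg = RatioScreenConfig(early_period={1.0}, late_period={10.0})
        res = screen(m, cfg)
        assert res[0].degenerate
        assert np.isinf(res[0].t) and res[0].p == 0.0

    def test_undersized_period_rejected(self):
        m = _period_matrix({"A": [1.0, 2.0], "B": [0.0, 0.0]}, {"A": [5.0], "B": [0.0]})
        cfg = RatioScreenConfig(early_period={1.0}, late_period={10.0})
        with pytest.raises(ValueError, match=">=2"):
            screen(m, cfg)

    def test_planted_pair_recovered_on_default_cohorts(self):
        """The surge/U-shaped pair is the designed best discriminator; it
        should dominate the screen across seeds."""
        hits = 0
        for seed in range(20):
            m, truth = simulate_cohort(CohortDesign(), default_paper_profiles(), seed=seed)
            best = screen(apply_grouping(m, DayGroupingRules()))[0]
            hits += (best.numerator_gene, best.denominator_gene) == truth.planted_pair
        assert hits >= 18
        assert truth.planted_pair == PLANTED_PAIR

    def test_config_validation(self):
        with pytest.raises(ValueError):
            RatioScreenConfig(alpha=0.0)
        with pytest.raises(ValueError):
            RatioScreenConfig(early_period={1.0}, late_period={1.0})
        with pytest.raises(ValueError):
            RatioScreenConfig(early_period=frozenset())
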