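"""PCA decomposition and contiguous early/middle/late segmentation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from moltmark import (
    CohortDesign,
    DayGroupingRules,
    ExpressionMatrix,
    apply_grouping,
    daily_scores,
    default_paper_profiles,
    normalize,
    run_pca,
    segment_days,
    simulate_cohort,
)


def _random_normalized_matrix(rng, n=20, p=6):
    values = pd.DataFrame(
        rng.normal(size=(n, p)),
        index=[f"s{i}" for i in range(n)],
        columns=[f"g{j}" for j in range(p)],
    )
    samples = pd.DataFrame(
        {"day": np.repeat(np.arange(1.0, n / 2 + 1), 2)[:n], "replicate": 1,
         "molt_phase": pd.NA},
        index=values.index,
    )
    return ExpressionMatrix(values=values, samples=samples, normalized=True)


class TestRunPCA:
    def test_two_perfectly_correlated_genes_are_rank_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        values = pd.DataFrame({"g1": x, "g2": 2 * x}, index=[f"s{i}" for i in range(12)])
        samples = pd.DataFrame(
            {"day": np.arange(12.0), "replicate": 1, "molt_phase": pd.NA},
            index=values.index,
        )
        m = ExpressionMatrix(values=values, samples=samples, normalized=True)
        model = run_pca(m, k=2)
        assert model.variance_fractions[0] == pytest.approx(1.0, abs=1e-12)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        model = run_pca(_random_normalized_matrix(rng), k=3)
        assert model.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_full_reconstruction_recovers_centered_matrix(self):
        rng = np.random.default_rng(2)
        m = _random_normalized_matrix(rng)
        model = run_pca(m, k=6)
        recon = model.scores.to_numpy() @ model.eigenvectors.to_numpy().T
        centered = m.values.to_numpy() - m.values.to_numpy().mean(axis=0)
        assert np.max(np.abs(recon - centered)) < 1e-9

    def test_eigenvectors_orthonormal_and_sign_fixed(self):
        rng = np.random.default_rng(3)
        model = run_pca(_random_normalized_matrix(rng), k=6)
        V = model.eigenvectors.to_numpy()
        assert np.allclose(V.T @ V, np.eye(6), atol=1e-10)
        for j in range(V.shape[1]):
            assert V[np.argmax(np.abs(V[:, j])), j] > 0

    def test_agrees_with_sklearn_up_to_sign(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(4)
        m = _random_normalized_matrix(rng)
        model = run_pca(m, k=4)
        sk = PCA(n_components=4).fit(m.values.to_numpy())
        assert np.allclose(
            model.variance_fractions[:4], sk.explained_variance_ratio_, atol=1e-10
        )
        for j in range(4):
            ours = model.eigenvectors.to_numpy()[:, j]
            theirs = sk.components_[j]
            assert np.allclose(np.abs(ours @ theirs), 1.0, atol=1e-8)

    def test_unnormalized_input_and_bad_k_rejected(self, default_cohort):
        matrix, _ = default_cohort
        with pytest.raises(ValueError, match="normalized"):
            run_pca(matrix, k=2)
        norm = normalize(matrix)
        with pytest.raises(ValueError, match="k"):
            run_pca(norm, k=13)


class TestDailyScores:
    def test_single_sample_group_returns_its_scores(self):
        rng = np.random.default_rng(5)
        m = _random_normalized_matrix(rng, n=4, p=3)
        m.samples["day"] = [1.0, 2.0, 3.0, 4.0]
        model = run_pca(m, k=2)
        ds = daily_scores(model, m)
        assert np.allclose(ds.to_numpy(), model.scores[["PC1", "PC2"]].to_numpy())

    def test_matches_brute_force_average_of_projections(self, default_cohort):
        matrix, _ = default_cohort
        grouped = apply_grouping(normalize(matrix), DayGroupingRules())
        model = run_pca(grouped, k=2)
        ds = daily_scores(model, grouped)
        for dg in ds.index:
            ids = [s for s in grouped.values.index
                   if grouped.samples.loc[s, "day_group"] == dg]
            brute = model.scores.loc[ids, ["PC1", "PC2"]].mean()
            assert np.allclose(ds.loc[dg], brute, atol=1e-12)

    def test_pc1_daily_score_trends_monotonically_with_day(self):
        """PC1 captures overall molt-cycle progression: its daily score is
        strongly rank-correlated with day on default synthetic cohorts."""
        rhos = []
        for seed in range(10):
            m, _ = simulate_cohort(CohortDesign(), default_paper_profiles(), seed=seed)
            grouped = apply_grouping(normalize(m), DayGroupingRules())
            ds = daily_scores(run_pca(grouped, k=2), grouped)
            rho, _ = stats.spearmanr(ds.index.to_numpy(), ds["PC1"].to_numpy())
            rhos.append(abs(rho))
        assert np.mean(rhos) > 0.8


def _enumerate_best(points, n_segments=3):
    """Independent exhaustive enumerator over contiguous partitions."""
    D = len(points)
    best_cost, best_cuts = None, None
    for cuts in itertools.combinations(range(1, D), n_segments - 1):
        bounds = (0, *cuts, D)
        cost = 0.0
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            seg = points[lo:hi]
            cost += float(((seg - seg.mean(axis=0)) ** 2).sum())
        if best_cost is None or cost < best_cost - 1e-12:
            best_cost, best_cuts = cost, cuts
    return best_cuts


class TestSegmentDays:
    @staticmethod
    def _scores(points):
        return pd.DataFrame(points, columns=["PC1", "PC2"],
                            index=[float(d) for d in range(1, len(points) + 1)])

    def test_planted_three_cluster_geometry_recovered(self):
        rng = np.random.default_rng(0)
        pts = ([(-3.0, 0.0)] * 5 + [(0.0, 2.0)] * 4 + [(3.0, 0.0)] * 5)
        pts = np.array(pts) + rng.normal(scale=0.05, size=(14, 2))
        cuts, labels = segment_days(self._scores(pts))
        assert cuts == (5, 9)
        assert [labels[d] for d in (1.0, 5.0, 6.0, 9.0, 10.0, 14.0)] == [
            "early", "early", "middle", "middle", "late", "late",
        ]

    def test_identical_scores_tie_break_earliest(self):
        pts = np.zeros((6, 2))
        cuts, labels = segment_days(self._scores(pts))
        assert cuts == (1, 2)
        assert labels[1.0] == "early" and labels[2.0] == "middle"
        assert all(labels[float(d)] == "late" for d in range(3, 7))

    def test_matches_independent_enumerator_on_random_series(self):
        rng = np.random.default_rng(42)
        for D in range(3, 15):
            for _ in range(10):
                pts = rng.normal(size=(D, 2))
                cuts, _ = segment_days(self._scores(pts))
                assert cuts == _enumerate_best(pts)

    def test_objective_non_increasing_in_segment_count(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(10, 2))

        def cost(n_seg):
            cuts, _ = segment_days(self._scores(pts), n_seg)
            bounds = (0, *cuts, len(pts))
            return sum(
                float(((pts[lo:hi] - pts[lo:hi].mean(axis=0)) ** 2).sum())
                for lo, hi in zip(bounds[:-1], bounds[1:])
            )

        costs = [cost(n) for n in (1, 2, 3, 4, 5)]
        assert all(a >= b - 1e-12 for a, b in zip(costs, costs[1:]))

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError, match="day groups"):
            segment_days(self._scores(np.zeros((2, 2))), 3)

    def test_default_cohort_recovers_early_middle_late_periods(self, default_cohort):
        matrix, _ = default_cohort
        grouped = apply_grouping(normalize(matrix), DayGroupingRules())
        ds = daily_scores(run_pca(grouped, k=2), grouped)
        cuts, labels = segment_days(ds)
        # expected boundaries after days 5 and 9, within one day group
        assert abs(cuts[0] - 5) <= 1 and abs(cuts[1] - 9) <= 1
        assert labels[1.0] == "early" and labels[13.5] == "late"
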