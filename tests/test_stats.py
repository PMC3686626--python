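"""Stage-3 analysis tests: averaging, Friedman machinery, maxT post-hocs,
regression summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import friedmanchisquare

from fpbench.stats import (AnalysisError, RankMatrix, average_performance,
                           average_rank, categorize, category_matrix,
                           correlation_matrix, friedman_global,
                           pairwise_friedman, posthoc_pairwise, regress)


def make_rank_matrix(ranks, method="AUC"):
    ranks = np.asarray(ranks, float)
    t, r, k = ranks.shape
    return RankMatrix(method, [f"T{i}" for i in range(t)],
                      [f"FP{i}" for i in range(k)], ranks)


def random_rank_matrix(rng, n_targets=6, n_reps=10, k=4):
    """Exchangeable null: every repetition ranks the fingerprints by an
    independent random permutation."""
    ranks = np.empty((n_targets, n_reps, k))
    for t in range(n_targets):
        for r in range(n_reps):
            ranks[t, r] = rng.permutation(k) + 1.0
    return make_rank_matrix(ranks)


class TestAveraging:
    def _df(self, values):
        rows = []
        for (tgt, fp), vals in values.items():
            for rep, v in enumerate(vals):
                rows.append((tgt, "AUC", fp, rep, v, 1.0))
        return pd.DataFrame(rows, columns=["target", "method", "fingerprint",
                                           "repetition", "value", "rank"])

    def test_constant_and_alternating_means(self):
        df = self._df({("t1", "A"): [0.7] * 50,
                       ("t1", "B"): [0, 1] * 25})
        table = average_performance(df)["t1"]
        assert table.loc["AUC", "A"] == pytest.approx(0.7)
        assert table.loc["AUC", "B"] == pytest.approx(0.5)

    def test_matches_independent_mean(self):
        rng = np.random.default_rng(3)
        vals = {("t1", f"F{i}"): rng.random(20).tolist() for i in range(3)}
        table = average_performance(self._df(vals))["t1"]
        for (_, fp), v in vals.items():
            assert table.loc["AUC", fp] == pytest.approx(sum(v) / len(v))

    def test_incomplete_cells_rejected(self):
        df = self._df({("t1", "A"): [0.5] * 10, ("t1", "B"): [0.5] * 9})
        with pytest.raises(AnalysisError):
            average_performance(df)


class TestAverageRank:
    def test_unanimous_winner(self):
        ranks = np.tile([1.0, 2.0, 3.0], (4, 10, 1))
        s = average_rank(make_rank_matrix(ranks))
        assert s["FP0"] == 1.0 and s["FP2"] == 3.0

    def test_symmetric_wins_average_to_middle(self):
        ranks = np.empty((2, 2, 2))
        ranks[0] = [[1, 2], [1, 2]]
        ranks[1] = [[2, 1], [2, 1]]
        s = average_rank(make_rank_matrix(ranks))
        assert s["FP0"] == s["FP1"] == pytest.approx(1.5)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        rm = random_rank_matrix(rng, n_targets=10)
        s = average_rank(rm)
        brute = rm.ranks.mean(axis=1).mean(axis=0)
        assert np.allclose(s.to_numpy(), brute)


class TestFriedmanGlobal:
    def test_identical_mean_ranks_give_null_result(self):
        ranks = np.tile([2.0, 2.0, 2.0], (5, 10, 1))
        stat, p = friedman_global(make_rank_matrix(ranks))
        assert stat == 0.0 and p == 1.0

    def test_planted_winner_is_detected(self):
        rng = np.random.default_rng(1)
        k, t, r = 5, 20, 10
        ranks = np.empty((t, r, k))
        for ti in range(t):
            for ri in range(r):
                rest = rng.permutation(k - 1) + 2.0
                ranks[ti, ri] = np.concatenate([[1.0], rest])
        stat, p = friedman_global(make_rank_matrix(ranks))
        assert p < 0.05

    def test_matches_scipy_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(44)
        for _ in range(10):
            x = rng.random((8, 5))  # ties almost surely absent
            stat, p = friedman_global(make_rank_matrix(x[:, None, :]))
            ref_stat, ref_p = friedmanchisquare(*[x[:, j] for j in range(5)])
            assert stat == pytest.approx(ref_stat, rel=1e-10)
            assert p == pytest.approx(ref_p, rel=1e-10)

    def test_single_fingerprint_rejected(self):
        with pytest.raises(AnalysisError):
            friedman_global(make_rank_matrix(np.ones((4, 3, 1))))


class TestPairwiseFriedman:
    def test_matches_sign_statistic_closed_form(self):
        # without ties the k=2 Friedman statistic reduces to (sum_t s_t)^2 / m
        # with s_t = sign(y_t - x_t)
        rng = np.random.default_rng(17)
        x, y = rng.random(12), rng.random(12)
        stat, p = pairwise_friedman(x, y)
        s = np.sign(y - x)
        assert stat == pytest.approx(s.sum() ** 2 / len(x), abs=1e-10)
        assert 0 <= p <= 1

    def test_consistent_dominance_small_p(self):
        x = np.arange(20, dtype=float)
        y = x + 1.0
        stat, p = pairwise_friedman(x, y)
        assert p < 1e-4

    def test_identical_samples_give_p_one(self):
        x = np.arange(10, dtype=float)
        assert pairwise_friedman(x, x) == (0.0, 1.0)


class TestPosthocPairwise:
    def test_null_pair_is_category_X(self):
        rng = np.random.default_rng(0)
        rm = random_rank_matrix(rng, n_targets=6, n_reps=20, k=2)
        reports = posthoc_pairwise(rm, n_boot=20, n_adjust_resamples=200, seed=1)
        assert len(reports) == 1
        assert reports[0].category == "X"

    def test_planted_dominance_is_category_significant(self):
        ranks = np.empty((8, 20, 3))
        rng = np.random.default_rng(2)
        for t in range(8):
            for r in range(20):
                ranks[t, r] = [1.0, *(rng.permutation(2) + 2.0)]
        reports = posthoc_pairwise(make_rank_matrix(ranks), n_boot=20,
                                   n_adjust_resamples=400, seed=3)
        lookup = {frozenset(r.pair): r for r in reports}
        assert lookup[frozenset(("FP0", "FP1"))].category == "-"
        assert lookup[frozenset(("FP0", "FP2"))].category == "-"

    def test_fourteen_fingerprints_give_91_reports(self):
        rng = np.random.default_rng(5)
        rm = random_rank_matrix(rng, n_targets=4, n_reps=6, k=14)
        reports = posthoc_pairwise(rm, n_boot=3, n_adjust_resamples=50, seed=1)
        assert len(reports) == 91

    def test_adjusted_dominate_raw_and_preserve_order(self):
        rng = np.random.default_rng(7)
        rm = random_rank_matrix(rng, n_targets=6, n_reps=15, k=5)
        reports = posthoc_pairwise(rm, n_boot=10, n_adjust_resamples=300, seed=2)
        for b in range(10):
            raw = np.array([r.resampled_raw_pvalues[b] for r in reports])
            adj = np.array([r.resampled_adjusted_pvalues[b] for r in reports])
            assert np.all(adj >= raw - 1e-12)
            order = np.argsort(raw, kind="stable")
            assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_null_calibration_of_significant_calls(self):
        """Under an exchangeable null the fraction of '-' calls stays at or
        below the confidence level plus Monte-Carlo tolerance."""
        rng = np.random.default_rng(11)
        n_sig = n_pairs = 0
        for s in range(15):
            rm = random_rank_matrix(rng, n_targets=8, n_reps=20, k=4)
            reports = posthoc_pairwise(rm, n_boot=20, n_adjust_resamples=200,
                                       seed=s)
            n_pairs += len(reports)
            n_sig += sum(r.category == "-" for r in reports)
        assert n_sig / n_pairs <= 0.05 + 0.05

    def test_categories_partition(self):
        rng = np.random.default_rng(9)
        rm = random_rank_matrix(rng, n_targets=5, n_reps=10, k=4)
        reports = posthoc_pairwise(rm, n_boot=5, n_adjust_resamples=100, seed=4)
        assert all(r.category in "-Xo" for r in reports)
        mat = category_matrix(reports, rm.fingerprints)
        upper = [mat.iloc[i, j] for i, j in
                 itertools.combinations(range(4), 2)]
        assert all(c in "-Xo" for c in upper)

    def test_n_boot_too_small_rejected(self):
        rng = np.random.default_rng(1)
        with pytest.raises(AnalysisError):
            posthoc_pairwise(random_rank_matrix(rng), n_boot=1)

    def test_categorize_rules(self):
        assert categorize([0.01, 0.02]) == "-"
        assert categorize([0.2, 0.9]) == "X"
        assert categorize([0.01, 0.9]) == "o"


class TestRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        s = regress(x, x)
        assert (s.slope, s.intercept) == (pytest.approx(1.0), pytest.approx(0.0))
        assert s.r_squared == pytest.approx(1.0)
        assert s.rmse == pytest.approx(0.0, abs=1e-12)

    def test_constant_y_degenerate_case(self):
        s = regress(np.arange(5.0), np.full(5, 2.0))
        assert s.slope == 0.0 and s.r == 0.0 and s.rmse == 0.0

    def test_zero_variance_x_rejected(self):
        with pytest.raises(AnalysisError):
            regress(np.full(5, 1.0), np.arange(5.0))

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(21)
        x = rng.random(30)
        y = 2.0 * x + 0.3 + rng.normal(0, 0.05, 30)
        s = regress(x, y)
        xm, ym = x.mean(), y.mean()
        slope = np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2)
        intercept = ym - slope * xm
        r = np.sum((x - xm) * (y - ym)) / np.sqrt(
            np.sum((x - xm) ** 2) * np.sum((y - ym) ** 2))
        assert s.slope == pytest.approx(slope, abs=1e-10)
        assert s.intercept == pytest.approx(intercept, abs=1e-10)
        assert s.r == pytest.approx(r, abs=1e-10)
        assert s.r_squared == pytest.approx(r * r, abs=1e-10)

    @pytest.mark.parametrize("m,expected", [(7, 21), (14, 91), (2, 1)])
    def test_correlation_pair_counts(self, m, expected):
        rng = np.random.default_rng(m)
        table = pd.DataFrame(rng.random((12, m)),
                             index=[f"t{i}" for i in range(12)],
                             columns=[f"c{i}" for i in range(m)])
        assert len(correlation_matrix(table)) == expected

    def test_subset_filtering(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(rng.random((10, 2)),
                             index=[f"t{i}" for i in range(10)],
                             columns=["a", "b"])
        full = correlation_matrix(table)[("a", "b")]
        part = correlation_matrix(table, subset=[f"t{i}" for i in range(5)])
        assert part[("a", "b")] != full
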