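"""Stage 3 — analysis: averaging, fingerprint ranking across targets,
Friedman tests with bootstrap maxT post-hoc comparisons, and correlation
summaries.

The rank machinery treats targets as blocks.  Per repetition of the
screening experiment the fingerprints are ranked by their score (rank 1 =
best, average ranks for ties); per target those ranks are averaged over the
repetitions, and a tie-corrected global Friedman test asks whether any
fingerprint is consistently ranked better than the others across targets.

If the global test is significant, every fingerprint pair is compared
post hoc.  The per-target mean ranks are recomputed ``n_boot`` (default
100) times from repetition sets resampled with replacement; within each
bootstrap replicate all k(k-1)/2 pairwise comparisons are run and their
p-values multiplicity-adjusted with a Westfall-Young maxT resampling scheme
(sign-flipping the per-target rank differences jointly across pairs, which
preserves the within-target correlation structure).  Each pair thus
accumulates ``n_boot`` adjusted p-values whose position relative to the
confidence level alpha yields a three-class call:

    "-"  all adjusted p-values below alpha  (highly significant difference)
    "X"  all above alpha                    (no significant difference)
    "o"  mixed                              (significant around alpha)
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, linregress, rankdata

logger = logging.getLogger("fpbench")

ALPHA_DEFAULT = 0.05


class AnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Averaging

def average_performance(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-target table of mean performance over repetitions.

    ``df`` is the tidy frame from :func:`fpbench.metrics.evaluate`.  Returns
    {target: DataFrame} with methods as rows and fingerprints as columns.
    """
    _require_complete(df)
    out = {}
    for tgt, sub in df.groupby("target", sort=False):
        out[str(tgt)] = sub.pivot_table(index="method", columns="fingerprint",
                                        values="value", aggfunc="mean",
                                        sort=False)
    return out


def _require_complete(df: pd.DataFrame) -> None:
    counts = df.groupby(["target", "method", "fingerprint"])["value"].count()
    if counts.nunique() > 1:
        bad = counts[counts != counts.max()]
        raise AnalysisError(f"incomplete metric values: {bad.index.tolist()[:5]} ...")


# ---------------------------------------------------------------------------
# Rank matrix

@dataclass
class RankMatrix:
    """Per-repetition ranks of the fingerprints for one evaluation method.

    ``ranks`` has shape (targets, repetitions, fingerprints); each
    (target, repetition) slice sums to k(k+1)/2 up to average-rank ties.
    """

    method: str
    targets: list[str]
    fingerprints: list[str]
    ranks: np.ndarray

    @classmethod
    def from_evaluation(cls, df: pd.DataFrame, method: str) -> "RankMatrix":
        sub = df[df["method"] == method]
        if sub.empty:
            raise AnalysisError(f"no values for method {method!r}")
        targets = list(dict.fromkeys(sub["target"]))
        fps = list(dict.fromkeys(sub["fingerprint"]))
        reps = sorted(sub["repetition"].unique())
        wide = sub.pivot_table(index=["target", "repetition"],
                               columns="fingerprint", values="rank")
        arr = np.empty((len(targets), len(reps), len(fps)))
        for ti, tgt in enumerate(targets):
            block = wide.loc[tgt].reindex(index=reps, columns=fps)
            if block.isna().any().any():
                raise AnalysisError(
                    f"method {method!r}, target {tgt!r}: missing ranks")
            arr[ti] = block.to_numpy()
        return cls(method, [str(t) for t in targets], [str(f) for f in fps], arr)

    @property
    def per_target_mean_ranks(self) -> np.ndarray:
        """(targets, fingerprints) mean rank over repetitions."""
        return self.ranks.mean(axis=1)


def average_rank(rank_matrix: RankMatrix) -> pd.Series:
    """Mean over targets of the per-target mean ranks (lower = better)."""
    means = rank_matrix.per_target_mean_ranks.mean(axis=0)
    return pd.Series(means, index=rank_matrix.fingerprints,
                     name=rank_matrix.method)


# ---------------------------------------------------------------------------
# Friedman tests

def _friedman_from_matrix(x: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Friedman test on a (blocks, treatments) matrix.

    Returns (chi-square statistic, p-value from the chi-square
    approximation with k-1 degrees of freedom).  Uses the general
    tie-robust form: with within-block average ranks R_ij and column sums
    R_j, the statistic is (k-1) * sum_j (R_j - b(k+1)/2)^2 /
    (sum_ij R_ij^2 - b k (k+1)^2 / 4).
    """
    b, k = x.shape
    if k < 2:
        raise AnalysisError("Friedman test needs at least 2 treatments")
    if b < 2:
        raise AnalysisError("Friedman test needs at least 2 blocks")
    ranks = np.apply_along_axis(rankdata, 1, x)
    col_sums = ranks.sum(axis=0)
    ss_num = np.sum((col_sums - b * (k + 1) / 2.0) ** 2)
    denom = np.sum(ranks ** 2) - b * k * (k + 1) ** 2 / 4.0
    if denom == 0.0:  # all blocks fully tied
        return 0.0, 1.0
    stat = (k - 1) * ss_num / denom
    return float(stat), float(chi2.sf(stat, k - 1))


def friedman_global(rank_matrix: RankMatrix) -> tuple[float, float]:
    """Global Friedman test across targets on per-target mean ranks.

    Returns (statistic, p-value).  A small p-value indicates that at least
    one fingerprint is consistently ranked differently from the others.
    """
    return _friedman_from_matrix(rank_matrix.per_target_mean_ranks)


def pairwise_friedman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """k=2 tie-corrected Friedman test on paired per-target values.

    Equivalent to a sign-test-like statistic on the per-target differences.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise AnalysisError("paired samples must have equal length")
    return _friedman_from_matrix(np.column_stack([x, y]))


# ---------------------------------------------------------------------------
# Bootstrap maxT post-hoc

CATEGORY_SIG = "-"    # all adjusted p below alpha
CATEGORY_NOT = "X"    # all adjusted p above alpha
CATEGORY_MIXED = "o"  # mixed


@dataclass(frozen=True)
class PairwiseTestReport:
    pair: tuple[str, str]
    resampled_adjusted_pvalues: tuple[float, ...]
    category: str
    resampled_raw_pvalues: tuple[float, ...] = ()


def categorize(pvalues: Sequence[float], alpha: float = ALPHA_DEFAULT) -> str:
    p = np.asarray(pvalues, float)
    if np.all(p < alpha):
        return CATEGORY_SIG
    if np.all(p >= alpha):
        return CATEGORY_NOT
    return CATEGORY_MIXED


def posthoc_pairwise(rank_matrix: RankMatrix,
                     alpha: float = ALPHA_DEFAULT,
                     n_boot: int = 100,
                     n_adjust_resamples: int = 1000,
                     seed: int = 0,
                     global_significant: bool = True) -> list[PairwiseTestReport]:
    """All-pairs post-hoc comparison with bootstrap-resampled maxT p-values.

    For each of ``n_boot`` bootstrap replicates the repetition ranks are
    resampled with replacement per target (jointly across fingerprints, so
    within-repetition correlation is preserved) and the per-target mean
    ranks recomputed.  Within a replicate the statistic of pair (i, j) is
    |T_ij| = |sum_t (mean_rank_ti - mean_rank_tj)|; its null distribution
    comes from ``n_adjust_resamples`` random sign flips of the per-target
    difference vectors applied jointly to all pairs, and the maxT-adjusted
    p-value of the pair is the fraction of flips in which the *maximum*
    statistic over all pairs reaches |T_ij| (with the (1+count)/(1+n)
    permutation convention).  By construction adjusted p-values dominate
    the per-pair resampling p-values and preserve their ordering.
    """
    if n_boot < 2:
        raise AnalysisError(f"n_boot must be >= 2, got {n_boot}")
    if not global_significant:
        logger.warning("post-hoc comparisons requested although the global "
                       "test was not significant; treat results as exploratory")
    ranks = rank_matrix.ranks
    n_targets, n_reps, k = ranks.shape
    if k < 2:
        raise AnalysisError("need at least 2 fingerprints")
    pairs = list(itertools.combinations(range(k), 2))
    rng = np.random.default_rng(seed)
    adjusted = np.empty((n_boot, len(pairs)))
    raw = np.empty((n_boot, len(pairs)))
    for b in range(n_boot):
        idx = rng.integers(0, n_reps, size=(n_targets, n_reps))
        mean_ranks = np.take_along_axis(
            ranks, idx[:, :, None], axis=1).mean(axis=1)  # (targets, k)
        # per-target differences for every pair: (targets, n_pairs)
        diff = np.stack([mean_ranks[:, i] - mean_ranks[:, j]
                         for i, j in pairs], axis=1)
        t_obs = np.abs(diff.sum(axis=0))
        signs = rng.choice([-1.0, 1.0], size=(n_adjust_resamples, n_targets))
        null = np.abs(signs @ diff)              # (resamples, n_pairs)
        max_null = null.max(axis=1)
        denom = 1.0 + n_adjust_resamples
        raw[b] = (1.0 + (null >= t_obs[None, :]).sum(axis=0)) / denom
        adj = (1.0 + (max_null[:, None] >= t_obs[None, :]).sum(axis=0)) / denom
        # successive maximization: enforce monotonicity of the adjusted
        # p-values in the order of the raw ones (standard maxT step)
        order = np.argsort(raw[b], kind="stable")
        adj[order] = np.maximum.accumulate(adj[order])
        adjusted[b] = adj
    fps = rank_matrix.fingerprints
    return [PairwiseTestReport(
        pair=(fps[i], fps[j]),
        resampled_adjusted_pvalues=tuple(adjusted[:, p].tolist()),
        category=categorize(adjusted[:, p], alpha),
        resampled_raw_pvalues=tuple(raw[:, p].tolist()),
    ) for p, (i, j) in enumerate(pairs)]


def category_matrix(reports: Sequence[PairwiseTestReport],
                    order: Sequence[str]) -> pd.DataFrame:
    """Render the pairwise calls as an upper-triangular matrix (as in the
    significance table), rows/columns in the given fingerprint order."""
    mat = pd.DataFrame("", index=list(order), columns=list(order))
    lookup = {frozenset(r.pair): r.category for r in reports}
    for a, b in itertools.combinations(order, 2):
        mat.loc[a, b] = lookup.get(frozenset((a, b)), "")
    return mat


# ---------------------------------------------------------------------------
# Correlations

@dataclass(frozen=True)
class RegressionSummary:
    slope: float
    intercept: float
    r: float
    r_squared: float
    rmse: float


def regress(x: Sequence[float], y: Sequence[float]) -> RegressionSummary:
    """Ordinary least squares of y on x with the summary statistics used for
    method/fingerprint correlation tables.

    A constant y is a documented degenerate case (slope 0, r reported as 0);
    a constant x leaves the fit undefined and raises.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise AnalysisError(f"need >= 3 points, got {x.size}")
    if np.ptp(x) == 0.0:
        raise AnalysisError("zero variance in x: degenerate fit")
    if np.ptp(y) == 0.0:
        return RegressionSummary(0.0, float(y[0]), 0.0, 0.0, 0.0)
    fit = linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    rmse = math.sqrt(float(np.mean(resid ** 2)))
    return RegressionSummary(float(fit.slope), float(fit.intercept),
                             float(fit.rvalue), float(fit.rvalue ** 2), rmse)


def correlation_matrix(table: pd.DataFrame,
                       subset: Sequence[str] | None = None
                       ) -> dict[tuple[str, str], RegressionSummary]:
    """All pairwise regressions between the columns of a per-target value
    table (targets as rows, methods or fingerprints as columns).

    ``subset`` optionally restricts the targets (rows), e.g. to exclude one
    collection style from the fit.  m columns yield m(m-1)/2 summaries.
    """
    if subset is not None:
        table = table.loc[list(subset)]
    out = {}
    for a, b in itertools.combinations(table.columns, 2):
        out[(str(a), str(b))] = regress(table[a].to_numpy(), table[b].to_numpy())
    return out
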