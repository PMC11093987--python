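"""Gene-set comparison machinery.

Authored here: single-sample rank-based set scoring with a permutation null,
plain and covariate-matched (stratified-resampling) permutation tests for a
difference in means/medians, and empirical-tail count tests.  Classical tests
(Wilcoxon rank-sum, Kruskal-Wallis, Fisher's exact) and Benjamini-Hochberg
correction delegate to scipy / statsmodels.

Every permutation test reports both the raw null fraction ``p_raw`` (which can
be 0) and the add-one estimator ``p_addone = (b + 1) / (R + 1)`` (which cannot),
and is exactly reproducible from its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

Direction = Literal["greater", "less", "two-sided"]
DEFAULT_REPLICATES = 10_000


@dataclass(frozen=True)
class SetTestResult:
    """Outcome of one permutation test."""

    statistic_name: str
    observed: float
    null_mean: float
    p_raw: float
    p_addone: float
    R: int
    seed: int
    direction: Direction

    def __str__(self) -> str:  # compact report line
        return (
            f"{self.statistic_name}: obs={self.observed:.4g} "
            f"null_mean={self.null_mean:.4g} p={self.p_addone:.4g} "
            f"({self.direction}, R={self.R})"
        )


@dataclass(frozen=True)
class RankScore:
    """Single-sample normalized mean percentile rank of a gene set."""

    sample_id: str
    set_name: str
    mean_rank: float
    normalized_score: float  # in [0, 1]
    n_genes: int
    set_size: int


def _pvalues(null: np.ndarray, observed: float, direction: Direction) -> tuple[float, float]:
    R = len(null)
    if direction == "greater":
        b = int(np.sum(null >= observed))
    elif direction == "less":
        b = int(np.sum(null <= observed))
    elif direction == "two-sided":
        b_hi = int(np.sum(null >= observed))
        b_lo = int(np.sum(null <= observed))
        b = min(2 * min(b_hi, b_lo), R)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return b / R, (b + 1) / (R + 1)


# ---------------------------------------------------------------------------
# Rank-based single-sample scoring


def rank_set_score(
    values: pd.Series,
    gene_set: Sequence[str],
    sample_id: str = "sample",
    set_name: str = "set",
) -> RankScore:
    """Normalized mean percentile rank of ``gene_set`` within one sample.

    Values are ranked ascending 1..n with mean ranks for ties.  The mean rank
    of the m set members is mapped to [0, 1] by its attainable extremes
    (m+1)/2 and n - (m-1)/2: 1 means the set occupies the very top of the
    ranking, 0 the very bottom.
    """
    gene_set = list(gene_set)
    missing = [g for g in gene_set if g not in values.index]
    if missing:
        raise KeyError(f"set genes absent from values: {missing}")
    m = len(gene_set)
    if m < 2:
        raise ValueError("gene set must have >= 2 members")
    n = len(values)
    ranks = pd.Series(sps.rankdata(values.to_numpy()), index=values.index)
    mean_rank = float(ranks.loc[gene_set].mean())
    lo = (m + 1) / 2
    hi = n - (m - 1) / 2
    return RankScore(
        sample_id=sample_id,
        set_name=set_name,
        mean_rank=mean_rank,
        normalized_score=(mean_rank - lo) / (hi - lo),
        n_genes=n,
        set_size=m,
    )


def perm_pvalue_set_score(
    values: pd.Series,
    gene_set: Sequence[str],
    R: int = DEFAULT_REPLICATES,
    seed: int = 0,
    direction: Direction = "greater",
) -> SetTestResult:
    """Permutation p-value for the rank set score against random same-size sets."""
    if R < 100:
        logger.warning("R=%d replicates is small; p-values will be coarse", R)
    score = rank_set_score(values, gene_set)
    ranks = sps.rankdata(values.to_numpy())
    n, m = score.n_genes, score.set_size
    lo, hi = (m + 1) / 2, n - (m - 1) / 2
    rng = np.random.default_rng(seed)
    keys = rng.random((R, n))
    idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
    null = (ranks[idx].mean(axis=1) - lo) / (hi - lo)
    p_raw, p_addone = _pvalues(null, score.normalized_score, direction)
    return SetTestResult(
        statistic_name="rank_set_score",
        observed=score.normalized_score,
        null_mean=float(null.mean()),
        p_raw=p_raw,
        p_addone=p_addone,
        R=R,
        seed=seed,
        direction=direction,
    )


# ---------------------------------------------------------------------------
# Permutation difference tests


def _stat_fn(stat: str):
    if stat == "mean":
        return np.mean
    if stat == "median":
        return np.median
    raise ValueError(f"unknown statistic {stat!r}")


def _stratified_null(
    pool: np.ndarray,
    bins_pool: np.ndarray,
    counts_per_bin: Mapping[int, int],
    stat: str,
    R: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null distribution of stat(sampled pseudo-set) - stat(rest of pool).

    Each replicate draws, per covariate bin, as many pool members as the
    observed set has in that bin, without replacement.
    """
    fn = _stat_fn(stat)
    bin_indices = {
        b: np.flatnonzero(bins_pool == b) for b in counts_per_bin
    }
    for b, need in counts_per_bin.items():
        if len(bin_indices[b]) < need:
            raise ValueError(
                f"covariate bin {b} has {len(bin_indices[b])} candidates for "
                f"{need} set genes"
            )
    N = len(pool)
    m = sum(counts_per_bin.values())
    # per bin: R draws of `need` members without replacement, vectorized
    chosen_cols = []
    for b, need in counts_per_bin.items():
        members = bin_indices[b]
        keys = rng.random((R, len(members)))
        idx = (
            np.argpartition(keys, need - 1, axis=1)[:, :need]
            if need < len(members)
            else np.tile(np.arange(len(members)), (R, 1))
        )
        chosen_cols.append(members[idx])
    chosen = np.concatenate(chosen_cols, axis=1)  # (R, m)
    if stat == "mean":
        s = pool[chosen].sum(axis=1)
        return s / m - (pool.sum() - s) / (N - m)
    null = np.empty(R)
    mask = np.zeros(N, dtype=bool)
    for r in range(R):
        mask[:] = False
        mask[chosen[r]] = True
        null[r] = fn(pool[mask]) - fn(pool[~mask])
    return null


def _prepare_groups(
    feature: pd.Series, set_ids: Sequence[str], background_ids: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, int]:
    set_ids = list(set_ids)
    background_ids = list(background_ids)
    if set(set_ids) & set(background_ids):
        raise ValueError("set and background overlap")
    sv = feature.reindex(set_ids).to_numpy(dtype=float)
    bv = feature.reindex(background_ids).to_numpy(dtype=float)
    n_na = int(np.isnan(sv).sum() + np.isnan(bv).sum())
    if n_na:
        logger.info("dropping %d NA feature values", n_na)
    sv = sv[~np.isnan(sv)]
    bv = bv[~np.isnan(bv)]
    if len(sv) < 3:
        raise ValueError("set must have >= 3 genes with values")
    if len(bv) < 3:
        raise ValueError("background must have >= 3 genes with values")
    return sv, bv, n_na


def perm_diff_test(
    feature: pd.Series,
    set_ids: Sequence[str],
    background_ids: Sequence[str],
    stat: Literal["mean", "median"] = "mean",
    R: int = DEFAULT_REPLICATES,
    seed: int = 0,
    direction: Direction = "greater",
) -> SetTestResult:
    """Permutation test for stat(set) - stat(background).

    The null relabels genes: each replicate draws |set| genes without
    replacement from set + background and recomputes the difference.
    """
    sv, bv, _ = _prepare_groups(feature, set_ids, background_ids)
    fn = _stat_fn(stat)
    observed = float(fn(sv) - fn(bv))
    pool = np.concatenate([sv, bv])
    rng = np.random.default_rng(seed)
    null = _stratified_null(
        pool, np.zeros(len(pool), dtype=int), {0: len(sv)}, stat, R, rng
    )
    p_raw, p_addone = _pvalues(null, observed, direction)
    return SetTestResult(
        statistic_name=f"perm_diff_{stat}",
        observed=observed,
        null_mean=float(null.mean()),
        p_raw=p_raw,
        p_addone=p_addone,
        R=R,
        seed=seed,
        direction=direction,
    )


def matched_perm_diff_test(
    feature: pd.Series,
    set_ids: Sequence[str],
    background_ids: Sequence[str],
    covariate: pd.Series,
    n_bins: int = 10,
    stat: Literal["mean", "median"] = "mean",
    R: int = DEFAULT_REPLICATES,
    seed: int = 0,
    direction: Direction = "greater",
) -> SetTestResult:
    """Covariate-matched permutation test (stratified resampling).

    The pooled genes are binned by covariate quantiles (edges from the
    background); each null draw samples, per bin, the same number of genes as
    the observed set has in that bin.  With ``n_bins=1`` this reduces exactly
    to :func:`perm_diff_test` (same seed, same draws).
    """
    set_ids = [g for g in set_ids if not np.isnan(feature.get(g, np.nan))]
    background_ids = [g for g in background_ids if not np.isnan(feature.get(g, np.nan))]
    missing_cov = [g for g in (*set_ids, *background_ids) if g not in covariate.index]
    if missing_cov:
        raise KeyError(f"covariate missing for genes: {missing_cov[:5]}")
    sv, bv, _ = _prepare_groups(feature, set_ids, background_ids)
    fn = _stat_fn(stat)
    observed = float(fn(sv) - fn(bv))
    pool = np.concatenate([sv, bv])
    cov = np.concatenate(
        [covariate.reindex(set_ids).to_numpy(float), covariate.reindex(background_ids).to_numpy(float)]
    )
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins == 1:
        bins = np.zeros(len(pool), dtype=int)
    else:
        edges = np.quantile(
            covariate.reindex(background_ids).to_numpy(float),
            np.linspace(0, 1, n_bins + 1)[1:-1],
        )
        bins = np.digitize(cov, edges)
    set_bins = bins[: len(sv)]
    counts = {int(b): int(c) for b, c in zip(*np.unique(set_bins, return_counts=True))}
    for b, need in counts.items():
        n_bg = int(np.sum(bins[len(sv):] == b))
        if n_bg == 0:
            raise ValueError(f"covariate bin {b} has no background candidates")
    rng = np.random.default_rng(seed)
    null = _stratified_null(pool, bins, counts, stat, R, rng)
    p_raw, p_addone = _pvalues(null, observed, direction)
    return SetTestResult(
        statistic_name=f"matched_perm_diff_{stat}",
        observed=observed,
        null_mean=float(null.mean()),
        p_raw=p_raw,
        p_addone=p_addone,
        R=R,
        seed=seed,
        direction=direction,
    )


def tail_count_test(
    values: pd.Series,
    set_ids: Sequence[str],
    background: Sequence[float] | np.ndarray,
    tail: Literal["top5", "bottom5"] = "top5",
    R: int = DEFAULT_REPLICATES,
    seed: int = 0,
    q: float = 0.05,
) -> SetTestResult:
    """Is the set over-represented beyond the background's empirical 5% tail?

    Observed = number of set genes strictly beyond the background 95th (or
    5th) percentile; null = the same count for random same-size draws from
    the background.  The chance expectation m*q accompanies the result as
    ``null_mean``'s reference.
    """
    bg = np.asarray(background, dtype=float)
    bg = bg[~np.isnan(bg)]
    if bg.size == 0:
        raise ValueError("empty background")
    sv = values.reindex(list(set_ids)).to_numpy(dtype=float)
    sv = sv[~np.isnan(sv)]
    m = len(sv)
    if m < 3:
        raise ValueError("set must have >= 3 genes with values")
    if tail == "top5":
        thr = np.quantile(bg, 1 - q)
        observed = float(np.sum(sv > thr))
        beyond = bg > thr
    elif tail == "bottom5":
        thr = np.quantile(bg, q)
        observed = float(np.sum(sv < thr))
        beyond = bg < thr
    else:
        raise ValueError(f"unknown tail {tail!r}")
    rng = np.random.default_rng(seed)
    keys = rng.random((R, bg.size))
    idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
    null = beyond[idx].sum(axis=1).astype(float)
    p_raw, p_addone = _pvalues(null, observed, "greater")
    return SetTestResult(
        statistic_name=f"tail_count_{tail}",
        observed=observed,
        null_mean=float(null.mean()),
        p_raw=p_raw,
        p_addone=p_addone,
        R=R,
        seed=seed,
        direction="greater",
    )


# ---------------------------------------------------------------------------
# Classical tests (delegated)


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    alternative: Literal["two-sided", "greater", "less"] = "two-sided",
) -> float:
    """Unpaired Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Exact enumeration when the combined sample has <= 12 observations and no
    ties; otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group")
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method,
                           use_continuity=True)
    return float(res.pvalue)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> float:
    """Kruskal-Wallis rank-sum p-value (tie-corrected H, chi-square df=k-1)."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
    if all(np.array_equal(arrays[0], g) for g in arrays[1:]):
        return 1.0  # identical groups: H = 0 by construction
    return float(sps.kruskal(*arrays).pvalue)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p for a 2x2 contingency table."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (arr < 0).any():
        raise ValueError("negative entries")
    return float(sps.fisher_exact(arr, alternative="two-sided")[1])


def bh_adjust(pvals: Sequence[float] | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjustment, mapped back to input order."""
    arr = np.asarray(pvals, dtype=float)
    if ((arr < 0) | (arr > 1)).any() or np.isnan(arr).any():
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = multipletests(arr, method="fdr_bh")[1]
    if isinstance(pvals, pd.Series):
        return pd.Series(adjusted, index=pvals.index, name="q")
    return adjusted


def significance_tier(p: float) -> str:
    """ns / * / ** / *** encoding at the 0.05, 0.01, 0.001 cutpoints."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
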