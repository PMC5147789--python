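"""Expression coherence (EC) statistics with permutation nulls.

The workflow per (similarity measure, dataset):

1. :func:`calibrate_threshold` samples random gene pairs (default 500,000)
   and takes the 95th percentile of their scores as the co-expression call
   threshold, fixing the per-pair false-positive rate at 5%.
2. :func:`compute_ec` scores a gene set: EC is the fraction of its pairs
   whose similarity strictly exceeds the threshold (0 = no co-expressed
   pair, 1 = all pairs co-expressed). Only positive tails count: for signed
   measures a strongly negative correlation is not co-expression.
3. :func:`null_ec_distribution` randomizes category membership (default 100
   draws, size held fixed) to build the category-size-specific null EC
   distribution.
4. :func:`ec_percentile_and_call` ranks the observed EC in the null
   (mid-rank percentile) and calls the category "high EC" when it exceeds
   the empirical 95th percentile of the null.

For set-level measures (partial correlations, BN arc strengths) the pair
null is built from random gene *sets* of the evaluated category's size,
scoring the pairs within each random set, since those measures are defined
only within a set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import ExpressionMatrix
from .similarity import (
    PAIRWISE_MEASURES,
    SET_MEASURES,
    PairSimilarity,
    SimilarityError,
    mutual_information,
    pairwise_matrix,
)

DEFAULT_N_PAIRS = 500_000
DEFAULT_N_RANDOMIZATIONS = 100
DEFAULT_PERCENTILE = 95.0


class CoherenceError(ValueError):
    pass


@dataclass
class NullThreshold:
    measure: str
    dataset: str
    percentile: float
    value: float
    n_pairs: int
    seed: int
    set_size: int = None  # set-level measures only


@dataclass
class ECResult:
    ec: float
    n_total: int
    n_above: int
    n_missing: int = 0


@dataclass
class CoherenceResult:
    category_id: str
    size: int
    ec: float
    n_pairs: int
    n_above: int
    ec_percentile: float
    high_ec: bool
    measure: str
    dataset: str
    n_randomizations: int


def _sample_pair_indices(n_genes, n_pairs, rng):
    """Unordered random gene pairs, self-pairs excluded, repeats allowed."""
    total = n_genes * (n_genes - 1) // 2
    if n_pairs >= total and total <= 2_000_000:
        iu = np.triu_indices(n_genes, k=1)
        return iu[0], iu[1]
    i = rng.integers(0, n_genes, size=int(n_pairs * 1.1) + 8)
    j = rng.integers(0, n_genes, size=len(i))
    ok = i != j
    i, j = i[ok][:n_pairs], j[ok][:n_pairs]
    while len(i) < n_pairs:
        a = rng.integers(0, n_genes, size=n_pairs)
        b = rng.integers(0, n_genes, size=n_pairs)
        ok = a != b
        i = np.concatenate([i, a[ok]])[:n_pairs]
        j = np.concatenate([j, b[ok]])[:n_pairs]
    return i, j


def _standardize_rows(X):
    mu = np.nanmean(X, axis=1, keepdims=True)
    sd = np.nanstd(X, axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        Z = (X - mu) / sd
    return Z, (sd.ravel() > 0)


def score_random_pairs(expr: ExpressionMatrix, measure, n_pairs, seed,
                       chunk=200_000) -> np.ndarray:
    """Scores of randomly sampled gene pairs under a pairwise measure."""
    if measure not in PAIRWISE_MEASURES:
        raise CoherenceError(f"{measure!r} is not a pairwise measure")
    rng = np.random.default_rng(seed)
    X = expr.to_array()
    i, j = _sample_pair_indices(expr.n_genes, n_pairs, rng)
    if measure in ("pcc", "spearman"):
        if measure == "spearman":
            X = np.apply_along_axis(stats.rankdata, 1, X)
        if np.isnan(X).any():
            scores = np.array([_nan_pair_pcc(X[a], X[b]) for a, b in zip(i, j)])
        else:
            Z, ok = _standardize_rows(X)
            n = X.shape[1]
            scores = np.empty(len(i), dtype=float)
            for start in range(0, len(i), chunk):
                sl = slice(start, start + chunk)
                scores[sl] = np.einsum("ij,ij->i", Z[i[sl]], Z[j[sl]]) / n
            bad = ~(ok[i] & ok[j])
            scores[bad] = np.nan
    else:
        variant = measure.split("_")[1]
        scores = np.array([mutual_information(X[a], X[b], variant)
                           for a, b in zip(i, j)])
    return scores


def _nan_pair_pcc(x, y):
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 6 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        return np.nan
    return float(np.corrcoef(x[ok], y[ok])[0, 1])


def score_random_set_pairs(expr: ExpressionMatrix, measure, set_size, n_sets,
                           seed) -> np.ndarray:
    """Pooled within-set pair scores over random gene sets (set-level null)."""
    if measure not in SET_MEASURES:
        raise CoherenceError(f"{measure!r} is not a set-level measure")
    rng = np.random.default_rng(seed)
    genes = expr.gene_ids
    out = []
    for k in range(n_sets):
        chosen = rng.choice(len(genes), size=set_size, replace=False)
        ps = pairwise_matrix(expr, [genes[c] for c in chosen], measure,
                             seed=int(rng.integers(2 ** 31)))
        out.append(ps.pair_scores())
    return np.concatenate(out)


def calibrate_threshold(expr: ExpressionMatrix, measure="pcc",
                        percentile=DEFAULT_PERCENTILE,
                        n_pairs=DEFAULT_N_PAIRS, seed=0,
                        set_size=None, n_sets=100,
                        dataset="default") -> NullThreshold:
    """Empirical null-score percentile over random gene pairs.

    For set-level measures, pass ``set_size``: the null is then built from
    ``n_sets`` random gene sets of that size (scores pooled over within-set
    pairs).
    """
    if expr.n_genes < 2:
        raise CoherenceError("need at least 2 genes")
    if measure in SET_MEASURES:
        if set_size is None:
            raise CoherenceError(f"measure {measure!r} needs set_size")
        scores = score_random_set_pairs(expr, measure, set_size, n_sets, seed)
    else:
        total = expr.n_genes * (expr.n_genes - 1) // 2
        scores = score_random_pairs(expr, measure, min(n_pairs, total), seed)
    scores = scores[np.isfinite(scores)]
    if len(scores) == 0:
        raise CoherenceError("no usable pair scores (constant profiles?)")
    value = float(np.quantile(scores, percentile / 100.0, method="higher"))
    return NullThreshold(measure, dataset, percentile, value,
                         int(len(scores)), seed, set_size)


def compute_ec(pairs: PairSimilarity, threshold) -> ECResult:
    """EC = fraction of usable pairs with score strictly above the threshold."""
    thr = threshold.value if isinstance(threshold, NullThreshold) else float(threshold)
    if isinstance(threshold, NullThreshold) and threshold.measure != pairs.measure:
        raise CoherenceError(
            f"threshold measure {threshold.measure!r} != pairs measure {pairs.measure!r}")
    scores = pairs.pair_scores()
    finite = np.isfinite(scores)
    n_missing = int((~finite).sum())
    usable = scores[finite]
    if len(usable) == 0:
        return ECResult(float("nan"), 0, 0, n_missing)
    n_above = int((usable > thr).sum())
    return ECResult(n_above / len(usable), int(len(usable)), n_above, n_missing)


def ec_for_genes(expr: ExpressionMatrix, genes, measure, threshold,
                 seed=0) -> ECResult:
    """Convenience: pair scores for a gene set, then EC against a threshold."""
    pairs = pairwise_matrix(expr, genes, measure, seed=seed)
    return compute_ec(pairs, threshold)


def null_ec_distribution(expr: ExpressionMatrix, category_size,
                         threshold: NullThreshold,
                         n_randomizations=DEFAULT_N_RANDOMIZATIONS,
                         seed=0) -> np.ndarray:
    """ECs of random same-size gene sets (membership-randomization null)."""
    if category_size < 3:
        raise CoherenceError("category size must be >= 3")
    if category_size > expr.n_genes:
        raise CoherenceError("category size exceeds gene universe")
    rng = np.random.default_rng(seed)
    genes = expr.gene_ids
    out = np.empty(n_randomizations)
    for r in range(n_randomizations):
        chosen = rng.choice(len(genes), size=category_size, replace=False)
        res = ec_for_genes(expr, [genes[c] for c in chosen], threshold.measure,
                           threshold, seed=int(rng.integers(2 ** 31)))
        out[r] = res.ec
    return out


def ec_percentile_and_call(ec: float, null_ecs) -> tuple:
    """Mid-rank percentile of ec in the null; high-EC call at the 95th.

    percentile = 100 * (#null < ec + 0.5 * #null == ec) / #null; the call is
    strict: high_EC iff ec > the empirical (order-statistic) 95th percentile
    of the null distribution.
    """
    null_ecs = np.asarray(null_ecs, dtype=float)
    null_ecs = null_ecs[np.isfinite(null_ecs)]
    if len(null_ecs) == 0:
        raise CoherenceError("empty null EC distribution")
    less = float((null_ecs < ec).sum())
    equal = float((null_ecs == ec).sum())
    percentile = 100.0 * (less + 0.5 * equal) / len(null_ecs)
    cut = float(np.quantile(null_ecs, 0.95, method="higher"))
    return percentile, bool(ec > cut)


@dataclass
class CoherenceProfile:
    """Category x dataset EC results plus recovery summaries."""

    table: pd.DataFrame
    high_counts: pd.Series          # per dataset: number of high-EC categories
    union_count: int                # categories high in >=1 dataset
    cumulative_recovery: pd.Series  # union count as datasets are added in order


def coherence_profile(expr_by_dataset: dict, cats, measure="pcc",
                      percentile=DEFAULT_PERCENTILE, n_null_pairs=DEFAULT_N_PAIRS,
                      n_randomizations=DEFAULT_N_RANDOMIZATIONS,
                      seed=0) -> CoherenceProfile:
    """Full category x dataset EC-percentile profile.

    Thresholds are calibrated per dataset; null EC distributions are cached
    per (dataset, category size). Returns the long-format table, per-dataset
    high-EC counts, the union count, and the cumulative recovery curve as
    datasets are added one at a time in the given order.
    """
    if not expr_by_dataset:
        raise CoherenceError("need at least one dataset")
    rows = []
    high_sets = {}
    for ds_i, (ds_name, expr) in enumerate(expr_by_dataset.items()):
        ds_seed = int(np.random.SeedSequence([seed, ds_i]).generate_state(1)[0] % (2 ** 31))
        null_cache = {}
        high_sets[ds_name] = set()
        universe = set(expr.gene_ids)
        for cid in cats.category_ids():
            genes = [g for g in cats.members(cid) if g in universe]
            size = len(genes)
            if size < 3:
                rows.append((cid, size, np.nan, np.nan, np.nan, np.nan, False,
                             measure, ds_name))
                continue
            key = size
            if "threshold" not in null_cache:
                if measure in SET_MEASURES:
                    null_cache["threshold"] = {}
                else:
                    null_cache["threshold"] = calibrate_threshold(
                        expr, measure, percentile, n_null_pairs, ds_seed,
                        dataset=ds_name)
            if measure in SET_MEASURES:
                if size not in null_cache["threshold"]:
                    null_cache["threshold"][size] = calibrate_threshold(
                        expr, measure, percentile, n_null_pairs, ds_seed,
                        set_size=size, dataset=ds_name)
                thr = null_cache["threshold"][size]
            else:
                thr = null_cache["threshold"]
            if key not in null_cache:
                null_cache[key] = null_ec_distribution(
                    expr, size, thr, n_randomizations, seed=ds_seed + size)
            res = ec_for_genes(expr, genes, measure, thr, seed=ds_seed)
            if math.isnan(res.ec):
                rows.append((cid, size, np.nan, res.n_total, res.n_above,
                             np.nan, False, measure, ds_name))
                continue
            pct, high = ec_percentile_and_call(res.ec, null_cache[key])
            if high:
                high_sets[ds_name].add(cid)
            rows.append((cid, size, res.ec, res.n_total, res.n_above, pct,
                         high, measure, ds_name))
    table = pd.DataFrame(rows, columns=[
        "category_id", "size", "ec", "n_pairs", "n_above", "ec_percentile",
        "high_ec", "measure", "dataset"])
    high_counts = pd.Series({d: len(s) for d, s in high_sets.items()})
    union, cum = set(), {}
    for ds_name in expr_by_dataset:
        union |= high_sets[ds_name]
        cum[ds_name] = len(union)
    return CoherenceProfile(table, high_counts, len(union),
                            pd.Series(cum))


# ---------------------------------------------------------------------------
# Group comparisons of EC values


@dataclass
class GroupComparison:
    u_statistic: float
    p_value: float
    n_with: int
    n_without: int


def compare_ec_groups(ec_with, ec_without, alternative="two-sided") -> GroupComparison:
    """Mann-Whitney U test of EC values between two category groups."""
    ec_with = np.asarray(list(ec_with), dtype=float)
    ec_without = np.asarray(list(ec_without), dtype=float)
    if len(ec_with) == 0 or len(ec_without) == 0:
        return GroupComparison(float("nan"), float("nan"),
                               len(ec_with), len(ec_without))
    res = stats.mannwhitneyu(ec_with, ec_without, alternative=alternative)
    return GroupComparison(float(res.statistic), float(res.pvalue),
                           len(ec_with), len(ec_without))


def ec_covariate_correlation(ecs, covariate):
    """Pearson correlation of EC with a numeric covariate (e.g. size)."""
    ecs = np.asarray(list(ecs), dtype=float)
    cov = np.asarray(list(covariate), dtype=float)
    ok = np.isfinite(ecs) & np.isfinite(cov)
    if ok.sum() < 3:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(ecs[ok], cov[ok])
    return float(r), float(p)
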