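"""Pairwise gene-gene association measures.

Seven measures are supported, grouped by how they are computed:

* pairwise: Pearson (``pcc``), Spearman (``spearman``), normalized and
  adjusted mutual information on equal-frequency-binned profiles
  (``mi_normalized``, ``mi_adjusted``);
* set-level, defined only within a gene set: partial correlation by the
  regression-residual method (``pcor_residual``), partial correlation from a
  shrinkage estimate of the correlation matrix (``pcor_shrinkage``), and
  Bayesian-network arc strengths from hill-climbing structure search on the
  Gaussian BIC score (``bn_arcstrength``, scored as -log10 of the arc's
  regression-coefficient p-value, symmetrized by the max over directions).

All scores are oriented so that higher means stronger association. Pairs
with fewer than six shared finite values, or a zero-variance profile, are
flagged missing (NaN).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_mutual_info_score, normalized_mutual_info_score

from .datasets import MIN_SHARED_SAMPLES, ExpressionMatrix

MEASURES = (
    "pcc", "spearman", "pcor_residual", "pcor_shrinkage",
    "mi_normalized", "mi_adjusted", "bn_arcstrength",
)
PAIRWISE_MEASURES = ("pcc", "spearman", "mi_normalized", "mi_adjusted")
SET_MEASURES = ("pcor_residual", "pcor_shrinkage", "bn_arcstrength")


class SimilarityError(ValueError):
    pass


@dataclass
class PairSimilarity:
    """Symmetric pair scores for one measure over a gene set."""

    measure: str
    genes: list
    matrix: np.ndarray  # m x m symmetric, NaN = missing
    flags: dict = field(default_factory=dict)

    def score(self, a, b) -> float:
        i, j = self.genes.index(a), self.genes.index(b)
        return float(self.matrix[i, j])

    def pair_scores(self) -> np.ndarray:
        """Upper-triangle scores (including NaN placeholders)."""
        iu = np.triu_indices(len(self.genes), k=1)
        return self.matrix[iu]

    def iter_pairs(self):
        for i, j in itertools.combinations(range(len(self.genes)), 2):
            yield self.genes[i], self.genes[j], float(self.matrix[i, j])


# ---------------------------------------------------------------------------
# Pairwise measures


def _shared_finite(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def pcc(x, y) -> float:
    """Pearson correlation on pairwise-complete values; NaN when degenerate."""
    x, y = _shared_finite(x, y)
    if len(x) < MIN_SHARED_SAMPLES:
        return float("nan")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def spearman(x, y) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x, y = _shared_finite(x, y)
    if len(x) < MIN_SHARED_SAMPLES:
        return float("nan")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def _equal_frequency_bins(x, n_bins=None):
    """Labels from equal-frequency binning; bins collapse when values tie."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n_bins is None:
        n_bins = max(2, math.ceil(math.sqrt(n)))
    n_bins = min(n_bins, len(np.unique(x)))
    if n_bins < 2:
        return np.zeros(n, dtype=int)
    labels = pd.qcut(pd.Series(x).rank(method="first"), n_bins, labels=False)
    return np.asarray(labels, dtype=int)


def mutual_information(x, y, variant="normalized") -> float:
    """MI between equal-frequency-binned profiles, normalized or adjusted.

    ``normalized`` scales MI by sqrt(H(x) H(y)) into [0, 1]; ``adjusted``
    centers MI by its fixed-marginals permutation expectation and scales by
    mean entropy, correcting the sample-size inflation of raw MI.
    """
    if variant not in ("normalized", "adjusted"):
        raise SimilarityError(f"unknown MI variant {variant!r}")
    x, y = _shared_finite(x, y)
    if len(x) < MIN_SHARED_SAMPLES:
        return float("nan")
    lx = _equal_frequency_bins(x)
    ly = _equal_frequency_bins(y)
    if len(np.unique(lx)) < 2 or len(np.unique(ly)) < 2:
        return float("nan")
    if variant == "normalized":
        return float(normalized_mutual_info_score(lx, ly, average_method="geometric"))
    return float(adjusted_mutual_info_score(lx, ly, average_method="arithmetic"))


# ---------------------------------------------------------------------------
# Matrix-level helpers


def correlation_matrix(X: np.ndarray, method="pcc") -> np.ndarray:
    """Gene-gene correlation matrix (rows are genes), NaN-aware when needed."""
    X = np.asarray(X, dtype=float)
    if method == "spearman":
        X = np.apply_along_axis(stats.rankdata, 1, X)
    if np.isnan(X).any():
        return pd.DataFrame(X.T).corr(min_periods=MIN_SHARED_SAMPLES).to_numpy()
    sd = X.std(axis=1)
    out = np.full((X.shape[0], X.shape[0]), np.nan)
    ok = sd > 0
    if ok.sum() >= 2:
        out[np.ix_(ok, ok)] = np.corrcoef(X[ok])
    np.fill_diagonal(out, 1.0)
    return out


# ---------------------------------------------------------------------------
# Partial correlations (set-level)


def partial_correlation_residual(X: np.ndarray, genes=None) -> PairSimilarity:
    """Partial correlation by correlating pairwise regression residuals.

    For each pair (i, j), both profiles are regressed (least squares with
    intercept; pseudoinverse solution when collinear) on the remaining m-2
    genes and the residuals correlated. When m - 2 >= n_samples - 1 the
    problem is ill-posed: the pseudoinverse solution is used and the result
    flagged ``ill_posed``.
    """
    X = np.asarray(X, dtype=float)
    m, n = X.shape
    if m < 3:
        raise SimilarityError("partial correlation needs >=3 genes")
    genes = list(genes) if genes is not None else [f"v{i}" for i in range(m)]
    ill_posed = (m - 2) >= (n - 1)
    out = np.full((m, m), np.nan)
    np.fill_diagonal(out, 1.0)
    Z_full = X.T  # n x m
    ones = np.ones((n, 1))
    for i, j in itertools.combinations(range(m), 2):
        others = [k for k in range(m) if k not in (i, j)]
        Z = np.hstack([ones, Z_full[:, others]])
        coef, *_ = np.linalg.lstsq(Z, Z_full[:, [i, j]], rcond=None)
        resid = Z_full[:, [i, j]] - Z @ coef
        ri, rj = resid[:, 0], resid[:, 1]
        if np.std(ri) == 0 or np.std(rj) == 0:
            continue
        out[i, j] = out[j, i] = float(np.corrcoef(ri, rj)[0, 1])
    return PairSimilarity("pcor_residual", genes, out, {"ill_posed": ill_posed})


def _shrinkage_intensity(X: np.ndarray) -> float:
    """Analytic optimal shrinkage toward the identity correlation target.

    lambda* = sum var(r_ij) / sum r_ij^2 over off-diagonal entries, clipped
    to [0, 1] (Schafer-Strimmer estimator).
    """
    X = np.asarray(X, dtype=float)
    m, n = X.shape
    Xs = (X - X.mean(axis=1, keepdims=True))
    sd = Xs.std(axis=1, ddof=1)
    sd[sd == 0] = np.nan
    Xs = Xs / sd[:, None]
    # w_kij = x_ki x_kj ; r_ij = (n-1)^-1 sum_k w_kij * n/(n-1) convention
    W_mean = (Xs @ Xs.T) / (n - 1)            # r_ij
    w2_sum = (Xs ** 2) @ (Xs ** 2).T / 1.0    # sum_k w_kij^2
    var_r = (n / (n - 1.0) ** 3) * (w2_sum - n * (W_mean * (n - 1) / n) ** 2)
    iu = np.triu_indices(m, k=1)
    num = np.nansum(var_r[iu])
    den = np.nansum(W_mean[iu] ** 2)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 0.0, 1.0))


def partial_correlation_shrinkage(X: np.ndarray, genes=None, lam=None) -> PairSimilarity:
    """Partial correlation from a shrunken correlation matrix.

    The sample correlation matrix R is shrunk toward the identity,
    R* = (1 - lambda) R + lambda I, with the analytic optimal intensity
    (or an explicit ``lam``); R* is inverted and the negative inverse
    standardized into partial correlations. Any lambda > 0 guarantees
    invertibility.
    """
    X = np.asarray(X, dtype=float)
    m, n = X.shape
    if m < 3:
        raise SimilarityError("partial correlation needs >=3 genes")
    genes = list(genes) if genes is not None else [f"v{i}" for i in range(m)]
    R = correlation_matrix(X)
    if np.isnan(R).any():
        raise SimilarityError("missing correlations; shrinkage needs complete profiles")
    if lam is None:
        lam = _shrinkage_intensity(X)
    Rs = (1.0 - lam) * R + lam * np.eye(m)
    P = np.linalg.inv(Rs)
    d = np.sqrt(np.diag(P))
    pcor = -P / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    return PairSimilarity("pcor_shrinkage", genes, pcor, {"lambda": float(lam)})


# ---------------------------------------------------------------------------
# Bayesian network arc strengths (set-level)


def _bic_node_score(data, j, parents, cache):
    """Gaussian log-likelihood - 0.5 log(n) * params for one node."""
    key = (j, tuple(sorted(parents)))
    if key in cache:
        return cache[key]
    y = data[:, j]
    n = len(y)
    if parents:
        Z = np.hstack([np.ones((n, 1)), data[:, sorted(parents)]])
        coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
        rss = float(np.sum((y - Z @ coef) ** 2))
    else:
        rss = float(np.sum((y - y.mean()) ** 2))
    rss = max(rss, 1e-12)
    k = len(parents) + 2  # intercept + coefficients + variance
    score = -0.5 * n * (math.log(2 * math.pi * rss / n) + 1) - 0.5 * k * math.log(n)
    cache[key] = score
    return score


def _has_path(parents, src, dst):
    """True if dst is reachable from src following child edges."""
    stack, seen = [src], set()
    children = {}
    for child, ps in parents.items():
        for p in ps:
            children.setdefault(p, set()).add(child)
    while stack:
        node = stack.pop()
        if node == dst:
            return True
        if node in seen:
            continue
        seen.add(node)
        stack.extend(children.get(node, ()))
    return False


def _hill_climb(data, rng, max_iter=200, init_parents=None):
    m = data.shape[1]
    parents = {j: set() for j in range(m)} if init_parents is None else {
        j: set(ps) for j, ps in init_parents.items()
    }
    cache = {}
    total = sum(_bic_node_score(data, j, parents[j], cache) for j in range(m))
    for _ in range(max_iter):
        best_delta, best_move = 1e-9, None
        for i in range(m):
            for j in range(m):
                if i == j:
                    continue
                if i in parents[j]:
                    # delete i -> j
                    delta = (_bic_node_score(data, j, parents[j] - {i}, cache)
                             - _bic_node_score(data, j, parents[j], cache))
                    if delta > best_delta:
                        best_delta, best_move = delta, ("del", i, j)
                    # reverse i -> j
                    trial_parents = {k: set(v) for k, v in parents.items()}
                    trial_parents[j].discard(i)
                    if not _has_path(trial_parents, j, i):
                        delta = (
                            _bic_node_score(data, j, parents[j] - {i}, cache)
                            - _bic_node_score(data, j, parents[j], cache)
                            + _bic_node_score(data, i, parents[i] | {j}, cache)
                            - _bic_node_score(data, i, parents[i], cache)
                        )
                        if delta > best_delta:
                            best_delta, best_move = delta, ("rev", i, j)
                else:
                    # add i -> j (must stay acyclic)
                    if _has_path(parents, j, i):
                        continue
                    delta = (_bic_node_score(data, j, parents[j] | {i}, cache)
                             - _bic_node_score(data, j, parents[j], cache))
                    if delta > best_delta:
                        best_delta, best_move = delta, ("add", i, j)
        if best_move is None:
            break
        op, i, j = best_move
        if op == "add":
            parents[j].add(i)
        elif op == "del":
            parents[j].discard(i)
        else:
            parents[j].discard(i)
            parents[i].add(j)
        total += best_delta
    return parents, total


def _arc_pvalues(data, parents):
    """t-test p-value of each parent's coefficient in its child's regression."""
    n = data.shape[0]
    pvals = {}
    for j, ps in parents.items():
        if not ps:
            continue
        cols = sorted(ps)
        Z = np.hstack([np.ones((n, 1)), data[:, cols]])
        coef, *_ = np.linalg.lstsq(Z, data[:, j], rcond=None)
        resid = data[:, j] - Z @ coef
        dof = n - Z.shape[1]
        if dof <= 0:
            for i in cols:
                pvals[(i, j)] = np.nan
            continue
        s2 = float(resid @ resid) / dof
        try:
            cov = s2 * np.linalg.inv(Z.T @ Z)
        except np.linalg.LinAlgError:
            cov = s2 * np.linalg.pinv(Z.T @ Z)
        se = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
        tstat = coef / se
        p = 2 * stats.t.sf(np.abs(tstat), dof)
        for idx, i in enumerate(cols, start=1):
            pvals[(i, j)] = float(p[idx])
    return pvals


def bn_arc_strengths(X: np.ndarray, genes=None, seed=0, restarts=2,
                     max_iter=200) -> PairSimilarity:
    """Arc strengths from greedy hill-climbing Gaussian-BIC structure search.

    Variables are canonically ordered alphabetically by gene id before the
    search so results do not depend on input order; ``restarts`` additional
    seeded random-DAG starts guard against local optima. Each learned arc
    i -> j is scored as -log10 of the t-test p-value of i's coefficient in
    the regression of j on its parents; the pair score is the max over the
    two directions, and non-adjacent pairs score 0.
    """
    X = np.asarray(X, dtype=float)
    m, n = X.shape
    genes = list(genes) if genes is not None else [f"v{i}" for i in range(m)]
    order = np.argsort(np.asarray(genes, dtype=object))
    inv_order = np.argsort(order)
    flags = {}
    if m == 1:
        return PairSimilarity("bn_arcstrength", genes, np.zeros((1, 1)), flags)
    if n <= m:
        flags["small_sample"] = True
    data = X[order].T  # n x m, canonical variable order
    data = (data - data.mean(axis=0)) / np.where(data.std(axis=0) == 0, 1, data.std(axis=0))
    rng = np.random.default_rng(seed)
    best_parents, best_score = _hill_climb(data, rng, max_iter=max_iter)
    for _ in range(restarts):
        init = {j: set() for j in range(m)}
        perm = rng.permutation(m)
        for a in range(m):
            for b in range(a + 1, m):
                if rng.random() < 0.2:
                    init[perm[b]].add(perm[a])
        parents, score = _hill_climb(data, rng, max_iter=max_iter, init_parents=init)
        if score > best_score:
            best_parents, best_score = parents, score
    pvals = _arc_pvalues(data, best_parents)
    S = np.zeros((m, m))
    for (i, j), p in pvals.items():
        if np.isnan(p):
            continue
        strength = -math.log10(max(p, 1e-300))
        S[i, j] = max(S[i, j], strength)
        S[j, i] = S[i, j]
    S = S[np.ix_(inv_order, inv_order)]
    np.fill_diagonal(S, 0.0)
    return PairSimilarity("bn_arcstrength", genes, S, flags)


# ---------------------------------------------------------------------------
# Dispatch


def pairwise_matrix(expr: ExpressionMatrix, gene_set, measure: str,
                    seed=0) -> PairSimilarity:
    """All pair scores for a gene set under one measure.

    Pairwise measures are computed per pair; set-level measures (partial
    correlations, BN arc strengths) are computed jointly over the set.
    """
    if measure not in MEASURES:
        raise SimilarityError(f"unknown measure {measure!r}")
    genes = list(gene_set)
    sub = expr.subset(genes=genes)
    X = sub.to_array()
    m = len(genes)
    if measure in ("pcor_residual", "pcor_shrinkage") and m < 3:
        raise SimilarityError("partial correlation needs >=3 genes")
    if measure == "pcc":
        M = correlation_matrix(X, "pcc")
        return PairSimilarity("pcc", genes, M)
    if measure == "spearman":
        M = correlation_matrix(X, "spearman")
        return PairSimilarity("spearman", genes, M)
    if measure in ("mi_normalized", "mi_adjusted"):
        variant = measure.split("_")[1]
        M = np.full((m, m), np.nan)
        np.fill_diagonal(M, 1.0)
        for i, j in itertools.combinations(range(m), 2):
            M[i, j] = M[j, i] = mutual_information(X[i], X[j], variant)
        return PairSimilarity(measure, genes, M)
    if measure == "pcor_residual":
        return partial_correlation_residual(X, genes)
    if measure == "pcor_shrinkage":
        return partial_correlation_shrinkage(X, genes)
    return bn_arc_strengths(X, genes, seed=seed)


def write_pair_scores(pairs: PairSimilarity, path) -> None:
    rows = [(a, b, s, "missing" if np.isnan(s) else "")
            for a, b, s in pairs.iter_pairs()]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "score", "flag"]).to_csv(
        path, sep="\t", index=False)
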