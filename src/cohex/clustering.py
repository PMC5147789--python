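"""Co-expression clustering sweep and run-to-run consistency.

Five algorithm families partition genes by expression profile:

* ``kmeans`` — Lloyd's k-means on Euclidean distance;
* ``hierarchical`` — agglomerative clustering with average / complete / Ward
  linkage on Euclidean, 1-PCC or RBF-kernel distance, cut at k clusters;
* ``cmeans`` — fuzzy c-means (fuzzifier 2), hardened by maximum membership;
* ``kernel_kmeans_approx`` — Nystrom landmark approximation of the RBF
  kernel feature map followed by k-means in feature space;
* ``network_modules`` — weighted co-expression network modules: soft
  threshold power chosen by scale-free topology fit, unsigned adjacency
  |PCC|^beta, topological overlap (TOM) similarity, average-linkage tree on
  1 - TOM cut at k clusters.

A sweep crosses algorithm-parameter combinations with repeated seeded runs;
:func:`run_consistency` measures agreement between runs as the Pearson
correlation of co-membership indicators over sampled gene pairs (adjusted
Rand index is reported alongside).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.kernel_approximation import Nystroem
from sklearn.metrics import adjusted_rand_score

from .datasets import ExpressionMatrix
from .similarity import correlation_matrix

ALGORITHMS = ("kmeans", "hierarchical", "cmeans", "kernel_kmeans_approx",
              "network_modules")
DISTANCES = ("euclidean", "one_minus_pcc", "rbf_kernel")
LINKAGES = ("average", "complete", "ward")


class ClusteringError(ValueError):
    pass


@dataclass
class ClusteringRun:
    algorithm: str
    params: dict
    run_index: int
    seed: int
    labels: pd.Series  # gene_id -> cluster id (int)

    @property
    def combo_id(self) -> str:
        items = sorted((k, v) for k, v in self.params.items())
        return self.algorithm + "|" + ",".join(f"{k}={v}" for k, v in items)

    @property
    def run_id(self) -> str:
        return f"{self.combo_id}|run{self.run_index}"

    def n_clusters(self) -> int:
        return int(self.labels.nunique())

    def cluster_members(self) -> dict:
        return {int(c): idx.tolist()
                for c, idx in self.labels.groupby(self.labels).groups.items()}


# ---------------------------------------------------------------------------
# Distances


def _median_heuristic_gamma(X, rng, n_probe=500):
    """RBF gamma = 1 / (2 * median^2) of probed pairwise distances."""
    n = X.shape[0]
    idx = rng.choice(n, size=min(n, n_probe), replace=False)
    d = pdist(X[idx])
    med = np.median(d[d > 0]) if (d > 0).any() else 1.0
    return 1.0 / (2.0 * med ** 2)


def distance_matrix(X, distance, rng=None):
    if distance == "euclidean":
        return squareform(pdist(X))
    if distance == "one_minus_pcc":
        C = correlation_matrix(X)
        C = np.nan_to_num(C, nan=0.0)
        D = 1.0 - C
        np.fill_diagonal(D, 0.0)
        return np.clip(D, 0.0, None)
    if distance == "rbf_kernel":
        rng = rng or np.random.default_rng(0)
        gamma = _median_heuristic_gamma(X, rng)
        sq = squareform(pdist(X, "sqeuclidean"))
        D = 1.0 - np.exp(-gamma * sq)
        np.fill_diagonal(D, 0.0)
        return D
    raise ClusteringError(f"unknown distance {distance!r}")


# ---------------------------------------------------------------------------
# Fuzzy c-means (hardened)


def _cmeans_labels(X, k, rng, fuzzifier=2.0, max_iter=300, tol=1e-5):
    n = X.shape[0]
    U = rng.random((n, k)) + 1e-6
    U /= U.sum(axis=1, keepdims=True)
    exp = 2.0 / (fuzzifier - 1.0)
    for _ in range(max_iter):
        Um = U ** fuzzifier
        centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-12)
        # membership u_ic = 1 / sum_j (d_ic / d_ij)^(2/(m-1))
        inv = d2 ** (-exp / 2.0)
        U_new = inv / inv.sum(axis=1, keepdims=True)
        if np.max(np.abs(U_new - U)) < tol:
            U = U_new
            break
        U = U_new
    # harden: argmax membership, ties -> lowest cluster id (argmax default)
    return U.argmax(axis=1)


# ---------------------------------------------------------------------------
# Network modules (soft threshold + TOM)


def pick_soft_threshold(expr_or_corr, candidate_betas=None, r2_target=0.8,
                        n_bins=10):
    """Smallest soft-threshold power with adequate scale-free topology fit.

    For each candidate beta the unsigned adjacency a_ij = |r_ij|^beta gives
    connectivities k_i = sum_j a_ij; log10 frequency is regressed on log10
    binned connectivity and the scale-free fit index is R^2 (taken as 0 when
    the slope is non-negative). Returns ``(beta, fit_table, flagged)`` where
    ``flagged`` is True if no candidate reached ``r2_target`` (the argmax-R2
    beta is returned then).
    """
    candidate_betas = list(candidate_betas or range(1, 21))
    if not candidate_betas:
        raise ClusteringError("no candidate betas")
    if isinstance(expr_or_corr, ExpressionMatrix):
        A0 = np.abs(correlation_matrix(expr_or_corr.to_array()))
    else:
        A0 = np.abs(np.asarray(expr_or_corr, dtype=float))
    A0 = np.nan_to_num(A0, nan=0.0)
    np.fill_diagonal(A0, 0.0)
    rows = []
    for beta in candidate_betas:
        A = A0 ** beta
        k = A.sum(axis=1)
        if np.allclose(k, k[0]):
            rows.append((beta, 0.0, 0.0, True))
            continue
        k = k[k > 0]
        logk = np.log10(k)
        edges = np.linspace(logk.min(), logk.max() + 1e-9, n_bins + 1)
        which = np.digitize(logk, edges) - 1
        xs, ys = [], []
        for b in range(n_bins):
            sel = which == b
            if sel.sum() == 0:
                continue
            xs.append(np.mean(logk[sel]))
            ys.append(np.log10(sel.sum() / len(logk)))
        xs, ys = np.array(xs), np.array(ys)
        if len(xs) < 3:
            rows.append((beta, 0.0, 0.0, True))
            continue
        slope, intercept = np.polyfit(xs, ys, 1)
        pred = slope * xs + intercept
        ss_res = float(((ys - pred) ** 2).sum())
        ss_tot = float(((ys - ys.mean()) ** 2).sum())
        r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        fit = r2 if slope < 0 else 0.0
        rows.append((beta, fit, slope, False))
    table = pd.DataFrame(rows, columns=["beta", "fit_r2", "slope", "degenerate"])
    good = table[table.fit_r2 >= r2_target]
    if len(good):
        return int(good.beta.iloc[0]), table, False
    return int(table.beta.iloc[table.fit_r2.idxmax()]), table, True


def topological_overlap(A: np.ndarray) -> np.ndarray:
    """Unsigned TOM similarity; values in [0, 1], TOM_ii = 1."""
    A = np.asarray(A, dtype=float)
    np.fill_diagonal(A, 0.0)
    L = A @ A
    k = A.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + A) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    tom = np.clip(tom, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def _network_module_labels(X, k, beta=None, r2_target=0.8):
    C = correlation_matrix(X)
    if beta is None:
        beta, _, _ = pick_soft_threshold(np.abs(C), r2_target=r2_target)
    A = np.nan_to_num(np.abs(C), nan=0.0) ** beta
    tom = topological_overlap(A)
    D = 1.0 - tom
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    return hierarchy.fcluster(Z, t=k, criterion="maxclust") - 1, beta


# ---------------------------------------------------------------------------
# Single runs


def run_clustering(expr: ExpressionMatrix, algorithm: str, params: dict,
                   seed=0, run_index=0) -> ClusteringRun:
    """One seeded clustering run; deterministic given (params, seed).

    ``params`` may contain ``k`` (required except network_modules where it
    sets the tree cut), ``distance``, ``linkage``, ``beta``, ``fuzzifier``,
    ``landmarks``. Invalid combinations (e.g. Ward with a non-Euclidean
    distance, k >= number of genes) raise before any computation.
    """
    if algorithm not in ALGORITHMS:
        raise ClusteringError(f"unknown algorithm {algorithm!r}")
    params = dict(params)
    k = int(params.get("k", 0))
    X = expr.to_array()
    # canonical gene order for run invariance to input order
    order = np.argsort(np.asarray(expr.gene_ids, dtype=object))
    genes_sorted = [expr.gene_ids[i] for i in order]
    X = X[order]
    n = X.shape[0]
    if k < 1 or k > n:
        raise ClusteringError(f"k={k} invalid for {n} genes")
    rng = np.random.default_rng(seed)
    distance = params.get("distance", "euclidean")
    if distance not in DISTANCES:
        raise ClusteringError(f"unknown distance {distance!r}")
    if algorithm == "kmeans":
        if distance != "euclidean":
            raise ClusteringError("kmeans supports only euclidean distance")
        km = KMeans(n_clusters=k, random_state=int(rng.integers(2 ** 31)),
                    n_init=10)
        labels = km.fit_predict(X)
    elif algorithm == "hierarchical":
        linkage = params.get("linkage", "average")
        if linkage not in LINKAGES:
            raise ClusteringError(f"unknown linkage {linkage!r}")
        if linkage == "ward" and distance != "euclidean":
            raise ClusteringError("ward linkage requires euclidean distance")
        if linkage == "ward":
            Z = hierarchy.linkage(X, method="ward")
        else:
            D = distance_matrix(X, distance, rng)
            Z = hierarchy.linkage(squareform(D, checks=False), method=linkage)
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust") - 1
    elif algorithm == "cmeans":
        if distance != "euclidean":
            raise ClusteringError("cmeans supports only euclidean distance")
        labels = _cmeans_labels(X, k, rng,
                                fuzzifier=float(params.get("fuzzifier", 2.0)))
    elif algorithm == "kernel_kmeans_approx":
        landmarks = int(params.get("landmarks", min(1000, n)))
        gamma = _median_heuristic_gamma(X, rng)
        ny = Nystroem(gamma=gamma, n_components=min(landmarks, n),
                      random_state=int(rng.integers(2 ** 31)))
        F = ny.fit_transform(X)
        km = KMeans(n_clusters=k, random_state=int(rng.integers(2 ** 31)),
                    n_init=10)
        labels = km.fit_predict(F)
    else:  # network_modules
        labels, beta = _network_module_labels(
            X, k, beta=params.get("beta"),
            r2_target=float(params.get("r2_target", 0.8)))
        params["beta"] = int(beta)
    series = pd.Series(labels, index=genes_sorted, name="cluster_id")
    series = series.loc[expr.gene_ids]  # restore caller's gene order
    return ClusteringRun(algorithm, params, run_index, seed, series.astype(int))


def wss_curve(expr: ExpressionMatrix, k_values, seed=0, n_init=5) -> pd.Series:
    """Within-cluster sum of squares (k-means, best of n_init) per k."""
    X = expr.to_array()
    if max(k_values) > X.shape[0]:
        raise ClusteringError("max k exceeds number of genes")
    rng = np.random.default_rng(seed)
    out = {}
    for k in k_values:
        km = KMeans(n_clusters=int(k), n_init=n_init,
                    random_state=int(rng.integers(2 ** 31)))
        km.fit(X)
        out[int(k)] = float(km.inertia_)
    return pd.Series(out).sort_index()


def elbow_k(wss: pd.Series) -> int:
    """k with the largest second difference of the WSS curve."""
    w = wss.sort_index()
    if len(w) < 3:
        return int(w.index[0])
    second = w.values[:-2] - 2 * w.values[1:-1] + w.values[2:]
    return int(w.index[1:-1][int(np.argmax(second))])


# ---------------------------------------------------------------------------
# Consistency between runs


@dataclass
class ConsistencyResult:
    mean_agreement: float      # mean pairwise co-membership PCC
    mean_ari: float            # mean pairwise adjusted Rand index
    pair_table: pd.DataFrame   # per run-pair agreement values
    flagged: list = field(default_factory=list)


def run_consistency(runs, n_probe_pairs=100_000, seed=0) -> ConsistencyResult:
    """Mean pairwise agreement of clustering runs.

    For each run a binary co-membership indicator is built over a common
    seeded sample of gene pairs; agreement of two runs is the Pearson
    correlation of their indicators. Degenerate runs (constant indicator,
    e.g. everything in one cluster) are flagged and excluded from the mean.
    """
    runs = list(runs)
    if len(runs) < 2:
        raise ClusteringError("need >=2 runs")
    genes = runs[0].labels.index
    for r in runs[1:]:
        if not r.labels.index.equals(genes):
            r_sorted = r.labels.reindex(genes)
            if r_sorted.isna().any():
                raise ClusteringError("runs cover different gene universes")
    n = len(genes)
    rng = np.random.default_rng(seed)
    total = n * (n - 1) // 2
    if n_probe_pairs >= total:
        iu = np.triu_indices(n, k=1)
        i, j = iu
    else:
        i = rng.integers(0, n, size=int(n_probe_pairs * 1.2) + 8)
        j = rng.integers(0, n, size=len(i))
        ok = i != j
        i, j = i[ok][:n_probe_pairs], j[ok][:n_probe_pairs]
    indicators = []
    for r in runs:
        lab = r.labels.reindex(genes).to_numpy()
        indicators.append((lab[i] == lab[j]).astype(float))
    rows, flagged = [], []
    for a, b in itertools.combinations(range(len(runs)), 2):
        va, vb = indicators[a], indicators[b]
        if va.std() == 0 or vb.std() == 0:
            flagged.append((a, b))
            rows.append((a, b, np.nan,
                         adjusted_rand_score(runs[a].labels.reindex(genes),
                                             runs[b].labels.reindex(genes))))
            continue
        pcc = float(np.corrcoef(va, vb)[0, 1])
        ari = float(adjusted_rand_score(runs[a].labels.reindex(genes),
                                        runs[b].labels.reindex(genes)))
        rows.append((a, b, pcc, ari))
    table = pd.DataFrame(rows, columns=["run_a", "run_b", "agreement", "ari"])
    return ConsistencyResult(
        float(np.nanmean(table.agreement)) if table.agreement.notna().any() else float("nan"),
        float(np.nanmean(table.ari)),
        table, flagged)


# ---------------------------------------------------------------------------
# Sweep


def sweep(expr: ExpressionMatrix, sweep_config, seed=0):
    """Cross-product clustering sweep with deterministic per-run seeds.

    ``sweep_config`` is a list of grid dicts, each with keys ``algorithm``,
    ``params`` (mapping param name -> list of values) and optional ``runs``
    (repeat count, default 1). Returns ``(runs, manifest)``; invalid
    combinations are skipped with the reason recorded in the manifest.
    """
    runs, manifest = [], []
    counter = 0
    for grid in sweep_config:
        algorithm = grid["algorithm"]
        n_runs = int(grid.get("runs", 1))
        param_grid = grid.get("params", {})
        keys = sorted(param_grid)
        for combo_vals in itertools.product(*(param_grid[k] for k in keys)):
            params = dict(zip(keys, combo_vals))
            for run_index in range(n_runs):
                run_seed = int(np.random.SeedSequence([seed, counter]).generate_state(1)[0] % (2 ** 31))
                counter += 1
                try:
                    run = run_clustering(expr, algorithm, params,
                                         seed=run_seed, run_index=run_index)
                except ClusteringError as exc:
                    manifest.append({
                        "run_id": f"{algorithm}|{json.dumps(params, sort_keys=True)}|run{run_index}",
                        "algorithm": algorithm,
                        "params": json.dumps(params, sort_keys=True),
                        "run_index": run_index, "seed": run_seed,
                        "status": "skipped", "reason": str(exc)})
                    continue
                runs.append(run)
                manifest.append({
                    "run_id": run.run_id, "algorithm": algorithm,
                    "params": json.dumps(run.params, sort_keys=True),
                    "run_index": run_index, "seed": run_seed,
                    "status": "ok", "reason": ""})
    return runs, pd.DataFrame(manifest)


def write_labels(run: ClusteringRun, path, sidecar_path=None) -> None:
    df = run.labels.rename_axis("gene_id").reset_index()
    df.to_csv(path, sep="\t", index=False)
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump({"algorithm": run.algorithm, "params": run.params,
                       "run_index": run.run_index, "seed": run.seed}, fh,
                      indent=2, default=str)
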