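"""Cluster-category over-representation scoring and calibration.

Each (cluster, category) pair is scored by a one-sided Fisher's exact
(hypergeometric enrichment) test on the 2x2 membership table over the
clustered gene universe, Benjamini-Hochberg corrected, and summarized as the
over-representation score -log10(q); a score >= 1.3 corresponds to q < 0.05.
Treating cluster membership as a predictor of category membership gives
precision (overlap / cluster size), recall (overlap / category size) and
their harmonic mean F, computed for significant pairs.

Sweep-level aggregation finds per-category maxima over algorithm-parameter
combinations and the improvement over a designated baseline combination;
:func:`random_cluster_calibration` verifies that permuted (co-expression
free) data yield no significant scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust

from .clustering import ClusteringRun, run_clustering
from .datasets import ExpressionMatrix, FunctionalCategorySet
from .simulate import permute_within_genes

#: -log10(q) cutoff for a significant over-representation (q < 0.05).
SCORE_THRESHOLD = 1.3


class EnrichmentError(ValueError):
    pass


def fisher_overlap(cluster_genes, category_genes, universe):
    """One-sided enrichment p-value for cluster/category overlap.

    Returns ``((a, b, c, d), p)`` with a = overlap, b = cluster only,
    c = category only, d = neither; p is the upper hypergeometric tail
    P(X >= a), identical to the one-sided Fisher's exact test.
    """
    universe = set(universe)
    if not universe:
        raise EnrichmentError("empty universe")
    cluster = set(cluster_genes) & universe
    category = set(category_genes) & universe
    a = len(cluster & category)
    b = len(cluster) - a
    c = len(category) - a
    d = len(universe) - a - b - c
    p = float(stats.hypergeom.sf(a - 1, len(universe), len(category), len(cluster)))
    return (a, b, c, d), min(p, 1.0)


def _f_measure(precision, recall):
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def score_all(runs, cats: FunctionalCategorySet, universe,
              bh_scope="per_run") -> pd.DataFrame:
    """Score every cluster x category pair across clustering runs.

    BH correction is applied across all cluster x category tests within each
    run (``bh_scope="per_run"``, default) or across everything
    (``"global"``). F is computed only for significant pairs (score >=
    1.3); insignificant pairs carry NaN F. Returns a long DataFrame with
    contingency counts, p, q, score, precision, recall and F.
    """
    if bh_scope not in ("per_run", "global"):
        raise EnrichmentError(f"unknown bh_scope {bh_scope!r}")
    universe = set(universe)
    cat_members = {cid: set(cats.members(cid)) & universe
                   for cid in cats.category_ids()}
    rows = []
    for run in runs:
        clusters = run.cluster_members()
        for cl_id, cl_genes in clusters.items():
            cl_set = set(cl_genes) & universe
            for cid, members in cat_members.items():
                if len(members) == 0:
                    continue
                a = len(cl_set & members)
                b = len(cl_set) - a
                c = len(members) - a
                d = len(universe) - a - b - c
                p = float(stats.hypergeom.sf(a - 1, len(universe),
                                             len(members), len(cl_set)))
                precision = a / (a + b) if (a + b) else 0.0
                recall = a / (a + c) if (a + c) else 0.0
                rows.append((run.run_id, run.combo_id, run.algorithm,
                             cl_id, cid, a, b, c, d, min(p, 1.0),
                             precision, recall))
    df = pd.DataFrame(rows, columns=[
        "run_id", "combo_id", "algorithm", "cluster_id", "category_id",
        "a", "b", "c", "d", "p", "precision", "recall"])
    if df.empty:
        df["q"] = df["score"] = df["F"] = df["significant"] = []
        return df
    q = np.full(len(df), np.nan)
    if bh_scope == "per_run":
        for _, idx in df.groupby("run_id").groups.items():
            q[idx] = bh_adjust(df.loc[idx, "p"])
    else:
        q = bh_adjust(df["p"])
    df["q"] = q
    with np.errstate(divide="ignore"):
        df["score"] = -np.log10(np.maximum(df["q"], 1e-300))
    df["significant"] = df["score"] >= SCORE_THRESHOLD
    f = np.where(df["significant"],
                 [_f_measure(p_, r_) for p_, r_ in zip(df["precision"], df["recall"])],
                 np.nan)
    df["F"] = f
    return df


@dataclass
class CombinationSummary:
    per_category: pd.DataFrame   # per-category maxima, winner, deltas
    n_recovered: int             # significant in >=1 combination
    n_never_recovered: int
    n_single_combo: int          # recovered by exactly one combination


def best_over_combinations(scores: pd.DataFrame, baseline_combo=None,
                           all_categories=None) -> CombinationSummary:
    """Per-category maxima over algorithm-parameter combinations.

    For each category: the maximum over-representation score, F and
    precision over all runs, the winning combination, and the delta of the
    maximum score vs the designated ``baseline_combo`` (its best run; 0 when
    the baseline is absent). Also counts categories recovered (significant
    in >= 1 combination), never recovered, and recovered by exactly one
    combination.
    """
    if scores.empty:
        raise EnrichmentError("no scores")
    cats = list(all_categories) if all_categories is not None \
        else sorted(scores.category_id.unique())
    rows = []
    sig = scores[scores.significant]
    combos_per_cat = sig.groupby("category_id")["combo_id"].nunique()
    for cid in cats:
        sub = scores[scores.category_id == cid]
        if sub.empty:
            rows.append((cid, 0.0, np.nan, np.nan, None, 0.0, 0.0, 0))
            continue
        best = sub.loc[sub.score.idxmax()]
        base_score = 0.0
        if baseline_combo is not None:
            base = sub[sub.combo_id == baseline_combo]
            if len(base):
                base_score = float(base.score.max())
        rows.append((cid, float(best.score), float(sub.F.max()),
                     float(sub.precision.max()), best.combo_id,
                     float(best.score) - base_score, base_score,
                     int(combos_per_cat.get(cid, 0))))
    per_cat = pd.DataFrame(rows, columns=[
        "category_id", "max_score", "max_F", "max_precision",
        "best_combo", "delta_vs_baseline", "baseline_score",
        "n_significant_combos"])
    n_rec = int((per_cat.n_significant_combos >= 1).sum())
    return CombinationSummary(
        per_cat,
        n_recovered=n_rec,
        n_never_recovered=len(per_cat) - n_rec,
        n_single_combo=int((per_cat.n_significant_combos == 1).sum()),
    )


def random_cluster_calibration(expr: ExpressionMatrix,
                               cats: FunctionalCategorySet,
                               n_permuted_datasets=15,
                               k_values=(5, 50, 100), n_runs=2,
                               seed=0, bh_scope="per_run"):
    """Count significant over-representation scores on permuted data.

    Each permuted dataset destroys co-expression (within-gene sample
    shuffling); k-means clusters are then scored against the categories.
    Under the global null, BH should leave (essentially) no significant
    scores. Returns ``(n_significant, n_tests)``.
    """
    rng = np.random.default_rng(seed)
    universe = expr.gene_ids
    n_sig = n_tests = 0
    for d in range(n_permuted_datasets):
        permuted = permute_within_genes(expr, seed=int(rng.integers(2 ** 31)))
        runs = []
        for k in k_values:
            for r in range(n_runs):
                runs.append(run_clustering(
                    permuted, "kmeans", {"k": int(k)},
                    seed=int(rng.integers(2 ** 31)), run_index=r))
        df = score_all(runs, cats, universe, bh_scope=bh_scope)
        n_sig += int(df.significant.sum())
        n_tests += len(df)
    return n_sig, n_tests


def feature_enrichment(cats: FunctionalCategorySet, feature_table: pd.DataFrame,
                       universe) -> pd.DataFrame:
    """Fisher + BH enrichment of binary gene features within categories.

    ``feature_table`` is a boolean genes x features DataFrame. BH correction
    is applied across categories within each feature family. Returns a long
    DataFrame (category_id, feature, a, b, c, d, p, q, enriched).
    """
    universe = set(universe)
    missing = universe - set(feature_table.index)
    if missing:
        raise EnrichmentError(
            f"{len(missing)} universe genes absent from feature table")
    rows = []
    for feature in feature_table.columns:
        carriers = set(feature_table.index[feature_table[feature].astype(bool)]) & universe
        for cid in cats.category_ids():
            members = set(cats.members(cid)) & universe
            if not members:
                continue
            (a, b, c, d), p = fisher_overlap(members, carriers, universe)
            rows.append((cid, feature, a, b, c, d, p))
    df = pd.DataFrame(rows, columns=["category_id", "feature",
                                     "a", "b", "c", "d", "p"])
    if df.empty:
        df["q"] = df["enriched"] = []
        return df
    q = np.full(len(df), np.nan)
    for _, idx in df.groupby("feature").groups.items():
        q[idx] = bh_adjust(df.loc[idx, "p"])
    df["q"] = q
    df["enriched"] = df["q"] < 0.05
    return df
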