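"""Consistency-based candidate-gene ranking and phenotype validation.

A gene not annotated to a target category is a guilt-by-association
candidate when, across many clustering results, it repeatedly lands in a
cluster significantly enriched (over-representation score >= 1.3) for that
category. The consistency count — the number of clustering results
(algorithm x parameters x run) in which that happens — ranks candidates.

Validation compares a quantitative mutant phenotype (e.g. free leucine,
nmol/g fresh weight) between mutant classes with Mann-Whitney tests: exact
null distribution for small samples without ties, normal approximation with
tie correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import SCORE_THRESHOLD

PHENOTYPE_CLASSES = ("pathway_mutant", "candidate_mutant", "random_mutant",
                     "wild_type")

#: combined sample size at or below which the exact Mann-Whitney null is used
EXACT_MW_MAX_N = 20


class ValidationError(ValueError):
    pass


@dataclass
class CandidateGene:
    gene_id: str
    target_category: str
    consistency_count: int
    contributing_runs: list


def rank_candidates(scores: pd.DataFrame, runs, target_category: str,
                    category_members, min_consistency=10) -> list:
    """Rank non-member genes by cluster-consistency with a target category.

    For each clustering result, a gene scores one consistency point when it
    sits in a cluster whose over-representation score for the target
    category is >= 1.3 and that actually contains target-category genes
    (each run counts at most once per gene). Members of the target category
    are excluded. Returns candidates with count >= ``min_consistency``
    sorted by count descending, then gene id ascending.
    """
    members = set(category_members)
    target = scores[(scores.category_id == target_category) & scores.significant]
    if target.empty:
        return []
    runs_by_id = {r.run_id: r for r in runs}
    counted = {}
    for run_id, sub in target.groupby("run_id"):
        run = runs_by_id.get(run_id)
        if run is None:
            raise ValidationError(f"scores reference unknown run {run_id!r}")
        clusters = run.cluster_members()
        genes_this_run = set()
        for _, row in sub.iterrows():
            if row.a < 1:
                continue  # no target genes actually in the cluster
            genes_this_run.update(clusters[int(row.cluster_id)])
        for g in genes_this_run - members:
            counted.setdefault(g, []).append(run_id)
    out = [CandidateGene(g, target_category, len(rids), sorted(rids))
           for g, rids in counted.items() if len(rids) >= min_consistency]
    out.sort(key=lambda c: (-c.consistency_count, c.gene_id))
    return out


def candidates_to_frame(candidates, n_runs_examined) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.gene_id, c.consistency_count, n_runs_examined,
          ";".join(c.contributing_runs)) for c in candidates],
        columns=["gene_id", "consistency_count", "n_runs_examined",
                 "contributing_runs"])


def cluster_log_odds(cluster_genes, category_genes, universe,
                     reading="captured") -> float:
    """Log2 odds that a cluster concentrates category genes.

    ``reading="captured"`` (default): log2 of (fraction of category genes
    captured by the cluster) over (fraction of non-category genes captured).
    ``reading="within_cluster"``: log2 of (category rate inside the cluster)
    over (category rate outside it). Degenerate proportions return signed
    infinity.
    """
    universe = set(universe)
    cluster = set(cluster_genes) & universe
    category = set(category_genes) & universe
    a = len(cluster & category)
    if reading == "captured":
        num_n, num_d = a, len(category)
        den_n, den_d = len(cluster) - a, len(universe) - len(category)
    elif reading == "within_cluster":
        num_n, num_d = a, len(cluster)
        den_n = len(category) - a
        den_d = len(universe) - len(cluster)
    else:
        raise ValidationError(f"unknown reading {reading!r}")
    if num_d == 0 or den_d == 0:
        raise ValidationError("empty category or universe")
    num = num_n / num_d
    den = den_n / den_d
    if den == 0:
        return math.inf if num > 0 else math.nan
    if num == 0:
        return -math.inf
    return math.log2(num / den)


def phenotype_comparison(pheno: pd.DataFrame, test_class: str,
                         control_class: str, alternative="greater"):
    """Mann-Whitney comparison of phenotype values between two classes.

    Exact p-value when the combined sample size is <= 20 and there are no
    ties; otherwise the normal approximation with tie correction. Default
    one-sided alternative: test class values are greater.

    Returns ``(U, p)``.
    """
    x = pheno.loc[pheno["class"] == test_class, "value"].to_numpy(dtype=float)
    y = pheno.loc[pheno["class"] == control_class, "value"].to_numpy(dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("empty phenotype group")
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= EXACT_MW_MAX_N and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def consistency_vs_phenotype(candidates, pheno: pd.DataFrame,
                             bins=None) -> dict:
    """Phenotype distribution per consistency-count bin plus a trend test.

    ``bins`` is an optional ordered sequence of right-inclusive count bin
    edges; by default each distinct count is its own bin. Returns a dict
    with a per-bin summary table (bins with fewer than three genes flagged
    ``low_n``) and the Spearman rank correlation of count vs phenotype
    value with its p-value.
    """
    if not candidates:
        return {"summary": pd.DataFrame(
            columns=["bin", "n", "median", "mean", "low_n"]),
            "trend_rho": float("nan"), "trend_p": float("nan")}
    values = pheno.set_index("gene_id")["value"]
    rows = []
    counts, phen = [], []
    for c in candidates:
        if c.gene_id not in values.index:
            continue
        counts.append(c.consistency_count)
        phen.append(float(values.loc[c.gene_id]))
    counts = np.asarray(counts)
    phen = np.asarray(phen)
    if bins is None:
        labels = counts
    else:
        labels = np.digitize(counts, np.asarray(bins), right=True)
    for b in sorted(set(labels.tolist())):
        sel = labels == b
        rows.append((b, int(sel.sum()), float(np.median(phen[sel])),
                     float(np.mean(phen[sel])), bool(sel.sum() < 3)))
    summary = pd.DataFrame(rows, columns=["bin", "n", "median", "mean", "low_n"])
    if len(counts) >= 3 and len(set(counts.tolist())) > 1 and np.std(phen) > 0:
        rho, p = stats.spearmanr(counts, phen)
    else:
        rho, p = float("nan"), float("nan")
    return {"summary": summary, "trend_rho": float(rho), "trend_p": float(p)}
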