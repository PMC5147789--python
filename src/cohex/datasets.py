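"""Expression matrices, functional gene sets, and dataset-level operations.

The central containers are :class:`ExpressionMatrix` (a genes x samples table
of log2 intensities or log2 fold-changes with per-sample metadata) and
:class:`FunctionalCategorySet` (named gene sets such as metabolic pathways or
GO biological-process terms, each membership carrying an evidence code).

Operations cover TSV / GMT-style I/O, treatment-vs-control fold-change
contrasts with Benjamini-Hochberg correction, column-wise combination of
datasets on a common gene universe, and within-dataset homogeneity (the
median pairwise sample-sample Pearson correlation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust

log = logging.getLogger(__name__)

VALUE_KINDS = ("intensity", "fold_change")
EVIDENCE_CODES = ("experimental", "computational")

#: Pairs sharing fewer finite values than this are flagged missing; six is the
#: minimum for a meaningful rank correlation.
MIN_SHARED_SAMPLES = 6

#: Categories must have more than two genes to be analyzed.
MIN_CATEGORY_SIZE = 3


class DatasetError(ValueError):
    """Raised on malformed expression matrices or gene-set files."""


def _default_sample_meta(sample_ids, dataset="default"):
    return pd.DataFrame(
        {"dataset": dataset, "condition": "", "role": "series"},
        index=pd.Index(sample_ids, name="sample_id"),
    )


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values plus per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns. Values are
        log2 scale; NaN marks missing.
    value_kind
        ``"intensity"`` for absolute log2 intensities, ``"fold_change"`` for
        log2 treatment-vs-control contrasts.
    sample_meta
        Per-sample ``dataset``, ``condition`` and ``role`` (treatment /
        control / series); defaults to a single anonymous dataset.
    """

    values: pd.DataFrame
    value_kind: str = "intensity"
    sample_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.value_kind not in VALUE_KINDS:
            raise DatasetError(f"unknown value_kind {self.value_kind!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise DatasetError(f"duplicate gene ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise DatasetError(f"duplicate sample ids: {dups}")
        try:
            self.values = self.values.astype(float)
        except (TypeError, ValueError) as exc:
            raise DatasetError(f"non-numeric expression values: {exc}") from exc
        if self.sample_meta is None:
            self.sample_meta = _default_sample_meta(self.values.columns)
        else:
            missing = set(self.values.columns) - set(self.sample_meta.index)
            if missing:
                raise DatasetError(f"sample_meta missing samples: {sorted(missing)}")
            self.sample_meta = self.sample_meta.loc[self.values.columns]

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self):
        return self.values.index.tolist()

    @property
    def sample_ids(self):
        return self.values.columns.tolist()

    @property
    def n_genes(self):
        return self.values.shape[0]

    @property
    def n_samples(self):
        return self.values.shape[1]

    def subset(self, genes=None, samples=None) -> "ExpressionMatrix":
        vals = self.values
        if genes is not None:
            missing = [g for g in genes if g not in vals.index]
            if missing:
                raise DatasetError(f"genes not in matrix: {missing[:5]}")
            vals = vals.loc[list(genes)]
        if samples is not None:
            vals = vals[list(samples)]
        return ExpressionMatrix(vals, self.value_kind, self.sample_meta.loc[vals.columns])

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# TSV I/O


def write_expression(expr: ExpressionMatrix, path, meta_path=None) -> None:
    """Write genes-rows / samples-columns TSV; optional sample-meta sidecar."""
    df = expr.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")
    if meta_path is not None:
        meta = expr.sample_meta.copy()
        meta.insert(0, "value_kind", expr.value_kind)
        meta.to_csv(meta_path, sep="\t")


def read_expression(path, value_kind="intensity", meta_path=None) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column gene id, header sample ids)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise DatasetError(f"empty expression file {path}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise DatasetError(f"expression file {path} has no data")
    if df.isna().all(axis=None):
        raise DatasetError(f"expression file {path} contains no numeric values")
    for col in df.columns:
        if df[col].dtype == object:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            if len(bad):
                raise DatasetError(
                    f"non-numeric cell {bad.iloc[0]!r} for gene {bad.index[0]!r} in column {col!r}"
                )
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        if "value_kind" in meta.columns:
            kinds = meta["value_kind"].unique()
            if len(kinds) != 1:
                raise DatasetError(f"inconsistent value_kind in {meta_path}: {kinds}")
            value_kind = kinds[0]
            meta = meta.drop(columns="value_kind")
    return ExpressionMatrix(df, value_kind, meta)


# ---------------------------------------------------------------------------
# Functional category sets


@dataclass
class FunctionalCategorySet:
    """Named gene sets with per-membership evidence codes.

    ``categories`` maps category id -> {gene_id: evidence}; evidence is
    ``"experimental"`` or ``"computational"``. Categories with fewer than
    three genes are dropped at construction (only categories with more than
    two genes are analyzed).
    """

    categories: dict
    kind: str = "pathway"
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self):
        kept = {}
        for cid, members in self.categories.items():
            for gene, ev in members.items():
                if ev not in EVIDENCE_CODES:
                    raise DatasetError(
                        f"unknown evidence code {ev!r} for gene {gene!r} in {cid!r}"
                    )
            if len(members) < MIN_CATEGORY_SIZE:
                log.info("dropping category %s with %d genes (<%d)", cid, len(members), MIN_CATEGORY_SIZE)
                continue
            kept[cid] = dict(members)
        self.categories = kept

    def __len__(self):
        return len(self.categories)

    def __contains__(self, cid):
        return cid in self.categories

    def category_ids(self):
        return list(self.categories)

    def members(self, cid):
        return list(self.categories[cid])

    def sizes(self) -> pd.Series:
        return pd.Series({c: len(m) for c, m in self.categories.items()}, dtype=int)

    def gene_universe(self):
        out = set()
        for members in self.categories.values():
            out.update(members)
        return out

    def restricted_to(self, universe) -> "FunctionalCategorySet":
        """Intersect all categories onto a gene universe, dropping small ones."""
        universe = set(universe)
        cats = {}
        n_dropped_genes = 0
        for cid, members in self.categories.items():
            keep = {g: ev for g, ev in members.items() if g in universe}
            n_dropped_genes += len(members) - len(keep)
            cats[cid] = keep
        if n_dropped_genes:
            log.info("restricted_to: dropped %d memberships outside universe", n_dropped_genes)
        return FunctionalCategorySet(cats, self.kind, dict(self.descriptions))


def filter_by_evidence(cats: FunctionalCategorySet, evidence: str) -> FunctionalCategorySet:
    """Restrict categories to members with the requested evidence code.

    ``evidence`` is ``"experimental"``, ``"computational"`` or ``"all"``.
    Categories falling to two or fewer genes are dropped (logged).
    """
    if evidence == "all":
        return FunctionalCategorySet(
            {c: dict(m) for c, m in cats.categories.items()}, cats.kind, dict(cats.descriptions)
        )
    if evidence not in EVIDENCE_CODES:
        raise DatasetError(f"unknown evidence filter {evidence!r}")
    out = {
        cid: {g: ev for g, ev in members.items() if ev == evidence}
        for cid, members in cats.categories.items()
    }
    return FunctionalCategorySet(out, cats.kind, dict(cats.descriptions))


def write_gene_sets(cats: FunctionalCategorySet, path) -> None:
    """Write GMT-extended lines: name, description, then gene|evidence tokens."""
    with open(path, "w") as fh:
        for cid, members in cats.categories.items():
            desc = cats.descriptions.get(cid, cats.kind)
            tokens = [f"{g}|{ev}" for g, ev in members.items()]
            fh.write("\t".join([cid, desc] + tokens) + "\n")


def read_gene_sets(path, kind="pathway") -> FunctionalCategorySet:
    cats, descs = {}, {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DatasetError(f"malformed gene-set line: {line[:60]!r}")
            cid, desc = parts[0], parts[1]
            members = {}
            for tok in parts[2:]:
                if "|" in tok:
                    gene, ev = tok.rsplit("|", 1)
                else:
                    gene, ev = tok, "experimental"
                if ev not in EVIDENCE_CODES:
                    raise DatasetError(f"unknown evidence code {ev!r} in {cid!r}")
                members[gene] = ev
            cats[cid] = members
            descs[cid] = desc
    return FunctionalCategorySet(cats, kind, descs)


# ---------------------------------------------------------------------------
# Fold changes


def compute_fold_changes(expr: ExpressionMatrix, contrasts: dict):
    """Contrast treatment vs control sample groups into a fold-change matrix.

    ``contrasts`` maps contrast id -> {"treatment": [sample ids],
    "control": [sample ids]}. Per gene and contrast, log2FC is the mean
    difference of log2 values; the p-value is a Welch two-sample t-test,
    BH-corrected across genes within each contrast. Groups of size one get
    the fold-change but a missing p-value.

    Returns
    -------
    (ExpressionMatrix, pandas.DataFrame)
        The fold-change matrix (one column per contrast, value_kind
        ``fold_change``) and a long table (gene_id, contrast, log2fc, p, q).
    """
    if expr.value_kind != "intensity":
        raise DatasetError("fold changes require an intensity matrix")
    fc_cols = {}
    rows = []
    meta_rows = {}
    for cid, groups in contrasts.items():
        treat = list(groups["treatment"])
        ctrl = list(groups["control"])
        if not treat or not ctrl:
            raise DatasetError(f"contrast {cid!r} has an empty group")
        t_vals = expr.values[treat].to_numpy(dtype=float)
        c_vals = expr.values[ctrl].to_numpy(dtype=float)
        lfc = np.nanmean(t_vals, axis=1) - np.nanmean(c_vals, axis=1)
        if len(treat) > 1 and len(ctrl) > 1:
            with np.errstate(invalid="ignore", divide="ignore"):
                p = stats.ttest_ind(t_vals, c_vals, axis=1, equal_var=False,
                                    nan_policy="omit").pvalue
            p = np.asarray(p, dtype=float)
        else:
            p = np.full(expr.n_genes, np.nan)
        q = bh_adjust(p)
        fc_cols[cid] = lfc
        meta_rows[cid] = {"dataset": expr.sample_meta.loc[treat[0], "dataset"],
                          "condition": cid, "role": "series"}
        rows.append(pd.DataFrame({
            "gene_id": expr.gene_ids, "contrast": cid,
            "log2fc": lfc, "p": p, "q": q,
        }))
    fc = pd.DataFrame(fc_cols, index=expr.values.index)
    meta = pd.DataFrame(meta_rows).T
    meta.index.name = "sample_id"
    result = pd.concat(rows, ignore_index=True)
    return ExpressionMatrix(fc, "fold_change", meta), result


# ---------------------------------------------------------------------------
# Dataset combination and homogeneity


def combine_datasets(matrices) -> ExpressionMatrix:
    """Column-concatenate datasets on the intersection of their gene ids."""
    matrices = list(matrices)
    if not matrices:
        raise DatasetError("no matrices to combine")
    kinds = {m.value_kind for m in matrices}
    if len(kinds) != 1:
        raise DatasetError(f"mixed value_kind: {sorted(kinds)}")
    common = matrices[0].values.index
    for m in matrices[1:]:
        common = common.intersection(m.values.index)
    if len(common) == 0:
        raise DatasetError("empty gene intersection")
    # keep first matrix's gene order
    common = [g for g in matrices[0].gene_ids if g in set(common)]
    n_dropped = sum(m.n_genes - len(common) for m in matrices)
    if n_dropped:
        log.info("combine_datasets: dropped %d gene rows outside intersection", n_dropped)
    vals = pd.concat([m.values.loc[common] for m in matrices], axis=1)
    if vals.columns.has_duplicates:
        raise DatasetError("duplicate sample ids across combined datasets")
    meta = pd.concat([m.sample_meta for m in matrices], axis=0)
    return ExpressionMatrix(vals, matrices[0].value_kind, meta)


def dataset_homogeneity(expr: ExpressionMatrix) -> float:
    """Median pairwise sample-sample Pearson correlation (samples over genes).

    Pairs involving a constant sample vector are excluded.
    """
    if expr.n_samples < 2:
        raise DatasetError("homogeneity needs >=2 samples")
    X = expr.to_array().T  # samples x genes
    if np.isnan(X).any():
        corr = pd.DataFrame(X.T).corr(min_periods=MIN_SHARED_SAMPLES).to_numpy()
    else:
        sd = X.std(axis=1)
        ok = sd > 0
        corr = np.full((X.shape[0], X.shape[0]), np.nan)
        if ok.sum() >= 2:
            corr_ok = np.corrcoef(X[ok])
            corr[np.ix_(ok, ok)] = corr_ok
    iu = np.triu_indices(X.shape[0], k=1)
    vals = corr[iu]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise DatasetError("no usable sample pairs for homogeneity")
    return float(np.median(vals))
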