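"""Synthetic expression data with planted pathway co-expression structure.

The generator follows a latent-factor model: each pathway p has one latent
factor f per dataset in which it is coherent, and a member gene's profile in
that dataset is

    x_gs = sqrt(rho) * f_ps + sqrt(1 - rho) * eps_gs

with f and eps standard Gaussian, so the expected Pearson correlation of two
member genes is exactly rho. Background genes, and member genes in datasets
where the pathway is not coherent, are pure noise. Values are interpreted as
log2-scale expression; correlation structure is the only aspect of real
microarray data the generator emulates.

Alongside expression, the module generates annotation sets with controllable
computational-evidence noise (decoy genes swapped in for true members),
mutant phenotype tables with a shift applied to pathway-gene and candidate
mutants, and within-gene sample permutations that destroy co-expression
while preserving per-gene value multisets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ExpressionMatrix, FunctionalCategorySet


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the scale of a large single-species microarray compendium
    (one "stress" dataset of 112 samples over ~22,000 genes, 225 annotated
    pathways); tests typically pass much smaller values explicitly.

    Attributes
    ----------
    rho
        Within-pathway latent-factor correlation in [0, 1); a scalar applied
        to every pathway or one value per pathway.
    coherent_in
        Per-pathway set of dataset names in which the pathway is coherent;
        ``None`` means coherent in all datasets.
    evidence_noise
        Fraction of each pathway's annotated members replaced by random
        decoy genes carrying "computational" evidence (true members keep
        "experimental" evidence). Default 0.49 reflects the error rate
        typical of purely sequence-similarity-based annotation transfer.
    phenotype_shift
        Additive shift (phenotype units) applied to mutants of pathway and
        designated candidate genes; default three noise SDs.
    """

    n_genes: int = 22000
    n_samples_per_dataset: dict = field(default_factory=lambda: {"stress": 112})
    n_pathways: int = 225
    pathway_size_range: tuple = (3, 30)
    rho: object = 0.6
    coherent_in: object = None
    evidence_noise: float = 0.49
    phenotype_shift: float = 30.0
    phenotype_baseline: float = 100.0
    phenotype_sd: float = 10.0
    seed: int = 0

    def __post_init__(self):
        rhos = np.atleast_1d(np.asarray(self.rho, dtype=float))
        if np.any((rhos < 0) | (rhos >= 1)):
            raise SimulationError("rho must lie in [0, 1)")
        if not 0.0 <= self.evidence_noise <= 1.0:
            raise SimulationError("evidence_noise must lie in [0, 1]")
        if self.n_genes < 1 or self.n_pathways < 1:
            raise SimulationError("counts must be >= 1")
        lo, hi = self.pathway_size_range
        if lo < 3 or hi < lo:
            raise SimulationError("pathway sizes must be >= 3 and min <= max")
        if not self.n_samples_per_dataset:
            raise SimulationError("need at least one dataset")
        if any(n < 1 for n in self.n_samples_per_dataset.values()):
            raise SimulationError("samples per dataset must be >= 1")

    def pathway_rho(self, index: int) -> float:
        rhos = np.atleast_1d(np.asarray(self.rho, dtype=float))
        return float(rhos[index % len(rhos)]) if len(rhos) > 1 else float(rhos[0])

    def pathway_coherent_in(self, pathway_id: str, index: int):
        names = list(self.n_samples_per_dataset)
        if self.coherent_in is None:
            return set(names)
        if isinstance(self.coherent_in, dict):
            return set(self.coherent_in.get(pathway_id, names))
        return set(self.coherent_in[index])


@dataclass
class PathwayTruth:
    pathway_id: str
    members: list
    rho: float
    coherent_in: set


@dataclass
class SyntheticBundle:
    """Everything downstream stages need, with the planted ground truth."""

    expression: ExpressionMatrix
    annotations: FunctionalCategorySet
    features: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: dict  # pathway_id -> PathwayTruth


def _gene_ids(n):
    return [f"g{i:06d}" for i in range(n)]


def _sample_ids(name, n):
    return [f"{name}_s{i:02d}" for i in range(n)]


def plan_pathways(cfg: SimulationConfig, rng: np.random.Generator) -> dict:
    """Assign disjoint member blocks and per-pathway rho / coherent datasets."""
    lo, hi = cfg.pathway_size_range
    sizes = rng.integers(lo, hi + 1, size=cfg.n_pathways)
    if sizes.sum() > cfg.n_genes:
        raise SimulationError(
            f"pathway sizes total {sizes.sum()} exceed n_genes={cfg.n_genes}"
        )
    genes = _gene_ids(cfg.n_genes)
    truth, start = {}, 0
    for i, size in enumerate(sizes):
        pid = f"pwy{i:04d}"
        truth[pid] = PathwayTruth(
            pathway_id=pid,
            members=genes[start:start + size],
            rho=cfg.pathway_rho(i),
            coherent_in=cfg.pathway_coherent_in(pid, i),
        )
        start += size
    return truth


def simulate_expression(cfg: SimulationConfig, truth=None):
    """Generate the latent-factor expression matrix.

    Returns ``(ExpressionMatrix, truth)`` where ``truth`` maps pathway id to
    its :class:`PathwayTruth`. Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    if truth is None:
        truth = plan_pathways(cfg, rng)
    names = list(cfg.n_samples_per_dataset)
    blocks, meta_frames = [], []
    gene_index = {g: i for i, g in enumerate(_gene_ids(cfg.n_genes))}
    for name in names:
        n_s = cfg.n_samples_per_dataset[name]
        X = rng.standard_normal((cfg.n_genes, n_s))
        for pt in truth.values():
            if name not in pt.coherent_in or pt.rho == 0.0:
                continue
            f = rng.standard_normal(n_s)
            rows = [gene_index[g] for g in pt.members]
            X[rows] = np.sqrt(pt.rho) * f + np.sqrt(1.0 - pt.rho) * X[rows]
        sids = _sample_ids(name, n_s)
        blocks.append(pd.DataFrame(X, index=_gene_ids(cfg.n_genes), columns=sids))
        meta_frames.append(pd.DataFrame(
            {"dataset": name, "condition": name, "role": "series"},
            index=pd.Index(sids, name="sample_id"),
        ))
    values = pd.concat(blocks, axis=1)
    expr = ExpressionMatrix(values, "intensity", pd.concat(meta_frames))
    return expr, truth


def simulate_annotations(cfg: SimulationConfig, truth) -> FunctionalCategorySet:
    """Annotation sets with a fraction of members replaced by decoys.

    Each pathway keeps ``(1 - evidence_noise)`` of its true members labeled
    "experimental"; the displaced members are replaced by background genes
    (drawn without replacement across pathways) labeled "computational",
    keeping pathway size constant.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    all_members = set()
    for pt in truth.values():
        all_members.update(pt.members)
    background = [g for g in _gene_ids(cfg.n_genes) if g not in all_members]
    rng.shuffle(background)
    pool = iter(background)
    cats = {}
    for pid, pt in truth.items():
        size = len(pt.members)
        n_noise = int(round(cfg.evidence_noise * size))
        n_noise = min(n_noise, size)
        kept = list(pt.members[: size - n_noise])
        members = {g: "experimental" for g in kept}
        try:
            for _ in range(n_noise):
                members[next(pool)] = "computational"
        except StopIteration:
            raise SimulationError("not enough background genes for decoys") from None
        cats[pid] = members
    return FunctionalCategorySet(cats, "pathway")


def simulate_features(cfg: SimulationConfig, truth, feature_names=("plastid", "motif_hit", "mirna_target"), rate=0.2):
    """Binary gene x feature table; features are independent Bernoulli flags."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    genes = _gene_ids(cfg.n_genes)
    data = rng.random((len(genes), len(feature_names))) < rate
    return pd.DataFrame(data, index=pd.Index(genes, name="gene_id"), columns=list(feature_names))


def simulate_phenotypes(cfg: SimulationConfig, truth, pathway_id,
                        candidate_genes=(), n_random_mutants=1000,
                        n_wild_type=184) -> pd.DataFrame:
    """Mutant phenotype table around a designated pathway.

    Mutants of the pathway's genes and of designated candidate genes get
    ``baseline + phenotype_shift + noise``; random-gene mutants and wild-type
    controls get ``baseline + noise``. Values are clipped at zero
    (concentration-type phenotype).

    Returns a DataFrame with columns (gene_id, class, value); classes are
    pathway_mutant / candidate_mutant / random_mutant / wild_type.
    """
    if pathway_id not in truth:
        raise SimulationError(f"unknown pathway id {pathway_id!r}")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    pt = truth[pathway_id]
    exclude = set(pt.members) | set(candidate_genes)
    background = [g for g in _gene_ids(cfg.n_genes) if g not in exclude]
    if n_random_mutants > len(background):
        raise SimulationError("n_random_mutants exceeds available background genes")
    random_genes = list(rng.choice(background, size=n_random_mutants, replace=False))
    rows = []
    def emit(gene, cls, shifted):
        mu = cfg.phenotype_baseline + (cfg.phenotype_shift if shifted else 0.0)
        val = max(0.0, mu + cfg.phenotype_sd * rng.standard_normal())
        rows.append((gene, cls, val))
    for g in pt.members:
        emit(g, "pathway_mutant", True)
    for g in candidate_genes:
        emit(g, "candidate_mutant", True)
    for g in random_genes:
        emit(g, "random_mutant", False)
    for i in range(n_wild_type):
        emit(f"WT{i:04d}", "wild_type", False)
    return pd.DataFrame(rows, columns=["gene_id", "class", "value"])


def permute_within_genes(expr: ExpressionMatrix, seed: int) -> ExpressionMatrix:
    """Independently permute each gene's values across samples.

    Preserves every gene's value multiset while destroying co-expression;
    used to build null datasets for cluster-enrichment calibration.
    """
    if expr.n_genes == 0 or expr.n_samples == 0:
        raise SimulationError("empty matrix")
    rng = np.random.default_rng(seed)
    X = expr.to_array().copy()
    for i in range(X.shape[0]):
        rng.shuffle(X[i])
    values = pd.DataFrame(X, index=expr.values.index, columns=expr.values.columns)
    return ExpressionMatrix(values, expr.value_kind, expr.sample_meta.copy())


def simulate_bundle(cfg: SimulationConfig, phenotype_pathway=None,
                    candidate_genes=(), n_random_mutants=1000,
                    n_wild_type=184) -> SyntheticBundle:
    """Generate expression, annotations, features and phenotypes in one go."""
    expr, truth = simulate_expression(cfg)
    annotations = simulate_annotations(cfg, truth)
    features = simulate_features(cfg, truth)
    if phenotype_pathway is None:
        phenotype_pathway = next(iter(truth))
    phenotypes = simulate_phenotypes(
        cfg, truth, phenotype_pathway, candidate_genes=candidate_genes,
        n_random_mutants=min(n_random_mutants, cfg.n_genes // 2),
        n_wild_type=n_wild_type,
    )
    return SyntheticBundle(expr, annotations, features, phenotypes, truth)


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "class", "value"}
    if not required.issubset(df.columns):
        raise SimulationError(f"phenotype table missing columns {required - set(df.columns)}")
    return df
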