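# Methods

## Expression coherence and its nulls

The central quantity is the expression coherence (EC) of a functional
category: the fraction of its gene pairs whose similarity strictly exceeds
a null-calibrated threshold. Two nulls are involved, and they answer
different questions.

The *pair-level* null fixes what "co-expressed" means for a single pair:
the threshold is the empirical 95th percentile (order statistic, ties
resolved upward) of similarity scores over randomly sampled gene pairs from
the full matrix universe — 500,000 pairs by default, sampled with
replacement across draws, self-pairs excluded. By construction ~5% of
independent pairs exceed it. The inequality at the threshold is strict, so
ties never count as co-expressed, and for signed measures only the positive
tail counts: a strongly negative correlation is not co-expression.

The *category-level* null fixes what "coherent category" means: category
membership is randomized (100 draws by default) with size held fixed, and
the observed EC is ranked in the resulting null EC distribution with
mid-rank handling of ties. A category is called high-EC when its EC
strictly exceeds the empirical 95th percentile of the null; the null is
size-specific and never pooled across sizes, because EC of small
categories is coarsely discrete and its null spread shrinks with size.

For measures defined only within a gene set — both partial correlations and
the Bayesian-network arc strengths — a "random pair" is not well-defined in
isolation, so the pair-level null is built from random gene *sets* of the
evaluated category's size, pooling the within-set pair scores. The
threshold cache is keyed by set size.

## Similarity measures

* **Pearson / Spearman** via `scipy.stats` on pairwise-complete values; a
  pair with fewer than 6 shared finite values (the minimum for a
  meaningful rank correlation) or a zero-variance profile is flagged
  missing and excluded from both EC counts.
* **Partial correlation, residual method**: for pair (i, j), both profiles
  are regressed on the remaining m−2 set members (least squares with
  intercept) and the residuals correlated. The regression is solved by
  pseudoinverse, which also covers exactly collinear predictors; when
  m−2 ≥ n−1 the problem is ill-posed and the result is flagged rather than
  refused, since large pathways are legitimately analyzed in this regime.
  The per-pair construction is deliberate: it remains correct when the full
  covariance matrix is singular (e.g. a gene that is exactly a sum of two
  others), where a precision-matrix shortcut would not.
* **Partial correlation, shrinkage**: the sample correlation matrix is
  shrunk toward the identity with the analytic optimal intensity
  λ\* = Σ var(r̂_ij) / Σ r̂_ij² (clipped to [0, 1]), inverted, and the
  negative inverse standardized. Any λ > 0 guarantees invertibility. As
  n/m → ∞, λ\* → 0 and the estimate converges to the residual method; this
  agreement is tested to 1e-6 at n = 400,000, m = 4.
* **Mutual information**: profiles are discretized into ⌈√n⌉
  equal-frequency bins (rank-based, so scale-free; bins collapse when
  distinct values run out), then `sklearn.metrics` computes
  MI/√(H(x)H(y)) ("normalized", in [0, 1]) and
  (MI − E[MI])/(mean(H) − E[MI]) ("adjusted", centered under the
  fixed-marginals permutation model so it is ≈ 0 for independent profiles
  at any sample size). Equal-frequency ⌈√n⌉ binning is a standard,
  assumption-light choice; the discretization is recorded in output
  metadata since MI values are not comparable across binning schemes.
* **Bayesian-network arc strengths**: a DAG over the gene set is learned
  by greedy hill-climbing on the Gaussian BIC score (add/delete/reverse
  moves, acyclicity-checked), with two additional seeded random-DAG
  restarts against local optima. Variables are canonically ordered
  alphabetically before the search so results are invariant to input gene
  order. Each learned arc i→j is scored as −log10 of the t-test p-value of
  i's coefficient in the regression of j on its parents; the pair score is
  the maximum over the two directions (the conservative pairwise
  reduction) and non-adjacent pairs score 0. −log10 is used throughout the
  package, consistent with the 1.3 ↔ q < 0.05 correspondence.

## Datasets

Fold-change matrices are derived per contrast as the difference of
treatment and control means on log2 values, with Welch two-sample t-test
p-values BH-corrected across genes within each contrast. This is a plain
two-sample contrast; moderated (empirical-Bayes) variance estimation is
intentionally out of scope since downstream EC consumes only the
fold-change vector. Groups of size one yield a fold-change with a missing
p-value.

Datasets combine by column concatenation on the intersection of gene ids
(dropped genes logged); homogeneity of a dataset is the median pairwise
sample–sample Pearson correlation, invariant to sample order and
per-sample additive offsets. Annotations are silently intersected onto the
active expression matrix's gene universe, with counts logged. Evidence
filtering ("experimental" vs "computational") drops categories falling to
two or fewer genes — only categories with more than two genes are ever
analyzed.

## Clustering sweep

Five algorithm families; all runs are deterministic given (parameters,
seed) and invariant to gene input order (canonical internal ordering):

* k-means (`sklearn`, Euclidean only, n_init = 10);
* hierarchical (scipy linkage: average / complete / Ward, the latter
  restricted to Euclidean; distances Euclidean, 1−PCC, or RBF-kernel
  1−exp(−γd²) with γ from the median-pairwise-distance heuristic), cut at
  k clusters;
* fuzzy c-means, fuzzifier 2 (the conventional default of the algorithm),
  hardened by maximum membership with ties to the lowest cluster id;
* approximate kernel k-means: seeded Nyström landmark feature map (default
  min(1000, n) landmarks, RBF bandwidth by the median heuristic) followed
  by k-means in feature space;
* network modules: soft-threshold power β chosen as the smallest candidate
  (1..20) whose log-log connectivity-frequency regression reaches the
  scale-free fit target R² ≥ 0.8 (argmax-R², flagged, otherwise; fit taken
  as 0 for non-negative slopes), unsigned adjacency |PCC|^β, topological
  overlap TOM = (L+a)/(min(k_i,k_j)+1−a) (in [0, 1], diagonal 1), and a
  fixed-k cut of the average-linkage tree on 1−TOM. The fixed-k cut stands
  in for dynamic tree cutting, which is out of scope; unsigned adjacency
  is used as the default network convention.

Run-to-run consistency is the Pearson correlation of binary co-membership
indicators over a seeded sample of gene pairs (default 100,000 — the full
pair set is infeasible at genome scale), averaged over run pairs;
"agreement between partitions" admits several readings, so the adjusted
Rand index is reported alongside. Degenerate runs (constant indicator) are
flagged and excluded from the mean. The within-cluster sum-of-squares curve
over k and its largest-second-difference elbow are provided for
orientation; no automatic model selection of k is attempted, since a
single "optimal" k demonstrably trades off against recovering individual
categories.

## Over-representation scoring

Cluster × category overlap is tested with the one-sided hypergeometric
tail (equivalent to one-sided Fisher's exact) over the universe of all
clustered genes — clusters are formed over all genes, so annotated-only
universes would overstate enrichment. BH correction is applied across all
cluster × category tests *within one clustering run* (the most common
convention, keeping runs comparable); global scope is available as a
configuration option. The over-representation score is −log10(q),
significant at ≥ 1.3. Precision, recall and F treat cluster membership as
a predictor of category membership; F is computed only for significant
pairs and reported as 0 (flagged by construction) when precision and
recall are both 0. Calibration on permuted data (within-gene sample
shuffling destroys co-expression but preserves per-gene value multisets)
verifies that the scoring yields no significant scores under the global
null; with many permuted datasets the occasional single BH rejection is
the expected behaviour of FDR control, not a defect.

## Candidate ranking and phenotype validation

For a target category, every non-member gene's consistency count is the
number of clustering results (algorithm × parameters × run, each counted
at most once per gene) in which it shares a significantly enriched cluster
(score ≥ 1.3, cluster actually containing target genes) with the target
category. Candidates are ranked by count, ties broken by gene id for
reproducibility. Cluster log-odds are reported under the
"fraction-of-category-captured" reading, log2[(a/|cat|)/(b/|non-cat|)],
with the "category rate inside vs outside the cluster" reading available
via a flag; degenerate proportions yield signed infinities.

Mann-Whitney comparisons of phenotype values use the exact null
distribution when the combined sample size is ≤ 20 and values are
tie-free (exact enumeration is cheap there), and the normal approximation
with tie correction otherwise; the default alternative is one-sided
(mutant values greater), matching the directional hypothesis of
degradation-pathway phenotypes.

## Synthetic data

The generator emulates only the statistical structure the analysis
consumes. Member genes of pathway p in a dataset where p is coherent
follow x = √ρ·f + √(1−ρ)·ε with f (per pathway × dataset) and ε standard
Gaussian, so the expected within-pathway pair correlation is exactly ρ;
background genes, and members in non-coherent datasets, are pure noise.
Values are interpreted as log2-scale expression. Annotation noise replaces
a fraction of true members with background decoys labeled
"computational" (true members keep "experimental"), holding pathway size
constant as size-matched analyses assume. Phenotypes are baseline + noise,
with an additive shift for pathway-gene and designated candidate mutants,
clipped at zero for concentration-type measurements.

Defaults mirror a large single-species microarray study: 22,000 genes, one
112-sample "stress" dataset, 225 pathways of 3–30 genes, evidence noise
0.49 (the error rate typical of annotation transfer by sequence similarity
alone), phenotype tables with 1000 random-gene mutants and 184 wild-type
controls. Where the emulated regime fixes no value, one was chosen once as
a realistic mid-range setting: ρ = 0.6 (a clearly but not perfectly
coherent pathway), phenotype baseline 100 with SD 10 in measurement units
and shift 30 (a 3σ effect). Tests and the acceptance script use smaller
stated sizes (hundreds to 2,000 genes, 30–50 samples) so the full suite
runs in minutes on one CPU.

What the generator does *not* emulate — probe-level noise, intensity
distributions, normalization artifacts, correlated backgrounds, shared
genes between pathways, hierarchical annotation structure — bounds what
passing tests show: they validate the statistical machinery
(calibration, power, recovery, determinism) under the factor model, not
performance on any real organism's data.

## Numerical conventions

* All empirical percentiles are order statistics (`method="higher"`);
  percentile ranks use mid-rank tie handling.
* Missing values: pairwise-complete in all correlations; pairs with < 6
  shared finite values are missing; missing pairs are excluded from both
  EC counts and logged.
* Every stochastic routine takes an explicit seed; sweeps and the
  acceptance script derive child seeds deterministically via
  `numpy.random.SeedSequence` (kept below 2³¹).
* −log10(q) is floored at q = 1e-300 to avoid infinities in tables.

## Known limitations

* The BN structure search is exact greedy hill-climbing with limited
  restarts; for gene sets beyond a few dozen members it is slow and may
  return local optima (mitigated, not eliminated, by restarts).
* The residual partial correlation is O(m²) regressions per set; for very
  large categories the shrinkage estimator is the practical choice.
* Adjusted MI's permutation-model expectation is computed by
  `scikit-learn` under fixed marginals of the *binned* labels; different
  bin counts (short profiles) change the adjustment.
* Fold-change p-values assume approximate normality within groups; with
  2–3 replicates per group the Welch test is underpowered and moderated
  alternatives would be preferable on real data.
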