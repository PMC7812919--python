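# Methods

`sliceglia` implements the computational workflow used to characterize
microglia states in organotypic brain-slice cultures from transcriptomic
readouts: panel-level timecourse profiling of the cultured tissue,
single-cell RNA-seq of FACS-sorted microglia, and bulk RNA-seq of
microglia from cytokine-treated slices. This note describes each stage's
model and assumptions, the parameters that matter, the synthetic data the
test suite runs on, and the numerical choices made where the design was
genuinely open.

## Quality control and normalization

Cells are discarded when (i) mitochondrial genes (identifier prefix
`mt-`, the mouse convention) occupy **more than 5%** of total UMI, (ii)
fewer than **400** genes are detected (count ≥ 1), or (iii) total UMI
exceed **30,000**. All three boundaries are strict in exactly that sense:
a cell sitting at 5%, at 400 genes, or at 30,000 UMI is retained. Because
only aggregate discard counts are usually reported, a cell failing
several rules is attributed to the first rule it fails, in the fixed
order mito → min-genes → max-UMI; the `QCReport` is therefore exhaustive
and reproducible. Filtering precedes normalization throughout.

Normalization rescales each cell (or sample) to a fixed total — counts
per million by default — optionally followed by `log2(x + 1)`. Layers are
tagged (`raw`, `cpm`, `log`, `centered`) and every stage checks the tag
it requires, so rank-based tests run on CPM, distance-based stages on
log, and nothing silently double-transforms. Bulk and panel matrices skip
cell QC but share the normalization contract.

## Signature scoring

Two row-wise readouts drive all heatmap-style summaries:

* **RobustCenterScale**: per gene, subtract the row median and divide by
  the raw median absolute deviation (no 1.4826 consistency constant —
  the scale is "MAD units", not an SD estimate). When MAD = 0 the divisor
  falls back to the row sample SD, then to 1.0, keeping outputs finite; a
  constant row maps to zeros. The fallback is logged.
* **Geneset mean z-score**: per gene, z-score its per-group mean
  expression across groups (sample SD, ddof = 1 — the common heatmap
  convention); per geneset and group, average the member genes' z-scores.
  Genes absent from the matrix are skipped and counted; a set with no
  gene present is an error rather than a silent zero. Group means are
  computed on CPM values before z-scoring (z-scores absorb any per-gene
  affine rescaling, so this choice affects nothing downstream of a
  monotone transform — a property the suite tests).

Cell-type marker sets are derived from a gene × cell-type score table by
a strict grand-mean cutoff (> 4 by default); a gene passing for several
cell types belongs to every corresponding set, since published marker
panels are not disjoint.

## PCA and gene-vs-covariate ranking

PCA is plain SVD on observation vectors of (optionally centered) log
expression; component signs are fixed by making each loading vector's
largest-magnitude entry positive, and are otherwise arbitrary. The
ranking stage computes, per gene, the Pearson correlation against a
numeric covariate — culture week, or a PC score — with a two-sided
p-value via the t-transform, BH FDR across tested genes, and a **scaled
slope**: the regression slope of robust-center-scaled expression on the
covariate, i.e. MAD units per covariate unit. Scaling the effect this
way keeps low-expressed genes from being down-weighted by their absolute
counts; the suite checks the slope is invariant to rescaling a gene.
Genes constant across observations have no defined correlation and are
excluded and flagged rather than tested. Because the planted timecourse
trends are log-linear, the pipeline correlates on the log layer, where
Pearson sees a straight line.

## Clustering and the over-clustering correction

Cells are clustered by Louvain community detection (igraph's multilevel
algorithm, seeded) on a k-nearest-neighbor graph built with Euclidean
distances in PC space (default 100 PCs of centered log-CPM, 20
neighbors, resolution 0.5; unweighted symmetrized edges). Modularity
optimization can split one biological population across clusters, so a
correction step follows:

1. per cluster, genes with per-cell average UMI **strictly above 0.2**
   (evaluated per cluster, where the selection happens) are ranked by
   the gene's **specificity score** — its cluster-mean UMI divided by
   the sum of its cluster means, so each gene's scores sum to 1 — and
   the top 100 taken, ties broken by lexicographic gene id for
   determinism;
2. the per-cluster lists are combined into one marker union;
3. Pearson correlation between cluster mean-UMI profiles over that
   union is computed for every pair; while any pair exceeds **0.8**, the
   highest pair is merged and profiles, markers and correlations are
   recomputed (merged profiles are exact cell-count-weighted means).

Iterating highest-pair-first with full recomputation is the conservative
generalization of a single-pass merge; recomputing markers after each
merge is the default, with a fixed-union mode available. Every merge is
recorded (pair, correlation) in a provenance that replays exactly; final
labels are renumbered 0..k−1 by descending size. Correlation on raw
mean-UMI profiles is the default, with a log-scale option. Batch
integration before clustering is an external hook, not reimplemented.

Cluster annotation computes geneset mean z-scores with clusters as
groups and assigns each cluster its argmax geneset, alongside one-vs-rest
Wilcoxon rank-sum marker tests (BH FDR); clusters under 3 cells are
skipped with a warning.

## Differential expression and set analysis

Two modes share one interface: a two-sided Wilcoxon rank-sum test
(normal approximation with tie and continuity correction; vectorized)
for cell-level data, and a per-gene linear model on `log2(CPM + 1)` with
a group indicator — equivalently a pooled-variance two-sample t-test on
the contrast — for population data. Genes with zero counts in both
groups are excluded and flagged. Fold changes are computed on the CPM
scale with a pseudocount of 1, `log2((mean_a + 1)/(mean_b + 1))`, which
keeps zero-mean genes finite. DEGs require |fold change| > 1.5 **and**
p or FDR < 0.05; both thresholds are strict. Multiple testing uses
Benjamini–Hochberg across the tested genes of a comparison.

Set algebra over two DEG sets reports, per direction, sizes,
intersection, union, uniques and the conserved fraction |A∩B|/|A|. The
cross-treatment quadrant analysis classifies every gene on the joint
fold-change plane: `shared_up/down` (DEG in the same direction in both
treatments), `a_only`/`b_only` (DEG in one, not a DEG in the other —
below the fold threshold there or not significant), `discordant`
(opposite-direction DEGs, reported separately so shared/unique totals
stay comparable), else `unchanged`; the categories partition the gene
universe. Geneset modulation reports the percentage of each set's
universe-mapped members per category, summing to 100.

A note on power at small n: with 4 samples per group (df = 6), genome-
wide BH correction leaves little power for 4-fold changes, so quadrant
recovery on 4v4 designs calls DEGs at p < 0.05 — the small-n arm of the
p-or-FDR rule — while bulk designs at the study scale (~10 samples per
group, the pipeline default) use FDR. Both arms are exposed by
`call_degs(alpha_is_fdr=...)`.

## Synthetic data

All generators draw counts from a negative binomial parameterized by
(mean μ, dispersion φ) with variance μ + φμ², sampled as Gamma–Poisson —
the standard RNA-seq count model and the one the DE stages assume. Every
generator is a pure function of its specification and seed, and returns
a `PlantedTruth` sufficient to score recovery without re-reading the
inputs.

* **Single cell** (default design): five populations — homeostatic,
  inflammatory, reactive, proliferative, neonatal — of 300 cells each
  over 2,000 genes; shared log-normal baseline (median ≈ 0.5 UMI/cell),
  a disjoint 50-gene program per population up-regulated 8-fold, NB
  dispersion 0.5, per-cell log-normal(0, 0.3) library-size factors, and
  a 10-gene `mt-` block retuned so the expected mitochondrial fraction
  is 2%. Program genes are drawn from the moderately expressed stratum
  (baseline > 0.3) so marker selection can see them.
* **Timecourse panel**: 5 timepoints (weeks 1–5) × 3 replicates, ~400
  genes, dispersion 0.1; trend genes move log-linearly (default 0.8
  log2/week — several-fold over the culture period, matching the scale
  of marker changes the design emulates) and transient genes follow an
  `amplitude · (t/τ) · exp(1 − t/τ)` pulse on the log2-mean scale,
  peaking at t = τ (default week 1) — an early inflammatory reaction
  that subsides.
* **Treatment bulk**: control plus two treatments, 10 samples per group
  (the scale of the cytokine experiment it emulates), 2,000 genes,
  dispersion 0.1; planted log2 fold changes of ±2 on disjoint shared /
  A-only / B-only blocks of 40–100 genes, i.e. a DE fraction of roughly
  10–15% as observed in strong cytokine responses.

What the generators deliberately do **not** model: doublets, ambient
RNA, batch structure, gene–gene correlation beyond the planted programs,
dropout beyond NB sampling, or the real panel's gene content. Passing
recovery tests therefore demonstrates that the pipeline's stages are
correct and calibrated under the count model they assume — not that they
are robust to every artifact of real single-cell data.

## Numerical choices and degenerate inputs

Ties in marker ranking break lexicographically; Louvain is seeded
(igraph draws from Python's `random`, which is saved and restored);
kNN edges are deduplicated and sorted before graph construction;
`n_pcs`/`n_components` beyond the matrix rank truncate with a warning;
zero-total observations are a named error in normalization; all-zero
genes get all-zero specificity rows; constant rows are finite after
RobustCenterScale; genes constant across groups contribute z = 0 to
signatures. Seeds fan out from one top-level seed via
`numpy.random.SeedSequence`, so every track is byte-reproducible.

## Problem sizes in the checks

The acceptance script re-derives the printed set arithmetic exactly and
runs the stochastic suites at: 100 seeds for merge recovery (1,000
genes, 200 cells/population), 50 seeds × 2,000 genes for each DE null,
10,000 genes for the ranking null, and 100 seeds for signature recovery
(600 genes, 80 cells/population, fold 4). These sizes give Monte-Carlo
error well inside the asserted margins while keeping a full run under a
minute on one core.

## Known limitations

The Wilcoxon p-values are asymptotic; at very small group sizes (≲5 per
group) exact enumeration would differ in the extreme tail. The linear
model assumes homoscedastic log-scale noise between groups. The merge
step's correlation is computed on mean profiles and therefore cannot
separate two populations that differ only in within-cluster covariance.
Harmony-style batch integration, UMAP/t-SNE layouts and pathway
enrichment are out of scope; hooks exist where they would slot in.
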