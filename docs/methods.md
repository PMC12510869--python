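# Methods

This note documents the models and procedures implemented in `uvrsig`,
the parameters that matter, what the synthetic-data generators do and do
not emulate, and the numerical choices made where the design was open.

## The signature-derivation model

The package traces a latent ultraviolet-response (UVR) transcriptional
program through tumor single-cell data. For one dataset with an
expression matrix X (genes × cells, log1p-normalized), a malignant-cell
annotation, and a seed UV-response gene set U:

1. Every cell receives a single-sample enrichment score of U
   (ssGSEA walk, below). This score is the observable proxy for the
   latent program activity.
2. **Gx** — genes whose expression across malignant cells is positively
   Spearman-correlated with the activity score: r > 0.3 and p < 0.05,
   strict inequalities. Correlation uses mid-ranks; p from the
   t-approximation (the screen always sees ≥10 cells).
3. **Gy** — genes upregulated in malignant versus non-malignant cells:
   two-sided Wilcoxon rank-sum per gene, Benjamini–Hochberg q over all
   tested genes, and log2 fold change of linear-scale means with a 1e-9
   pseudocount. Selection: logFC ≥ 0.30 and q < 1e-5. The default is
   sign-restricted (up only); an absolute-value mode exists because the
   thresholds are conventionally quoted as |logFC|. Negative linear
   means (possible only for centred input) are clamped at 0.
4. **Gn = Gx ∩ Gy** per dataset; the signature is the deduplicated
   union of Gn over datasets, with per-gene provenance counts.

These thresholds are deliberately strict (>, <): boundary genes are
excluded, and relaxing any threshold can only grow Gx, Gy and Gn — a
property the tests verify.

The correlation screen runs on malignant cells only by default
(`correlate_all_cells` switches to all cells); which population the
original workflow used is not documented, and malignant-only is the
choice consistent with intersecting against malignant DEGs.

## Enrichment scores

**ssGSEA.** Within each sample, genes get ascending mid-ranks; walking
down the genes in descending expression order, set members add
rank^α / Σ_set rank^α and non-members subtract 1/(N − |S|); the score is
the sum of the running difference over all N positions (the integrated
walk). α defaults to 0.25, the conventional exponent. With
`normalize=True` (default) the whole score matrix is divided by its
range. Scores depend only on within-sample ranks; ties are broken by
mid-rank, then stable gene order, for determinism.

**ECDF variant (GSVA-style).** Each gene's expression is first mapped to
its empirical-CDF statistic across samples (rank/n); each sample is then
scored by a weighted KS walk over genes ordered by that statistic, and
the score is max positive deviation + max negative deviation. This is a
simplified rank/ECDF reimplementation — no kernel density smoothing —
and is not expected to match any particular package numerically. It
needs ≥3 samples; for fewer, ssGSEA (purely within-sample) applies.

**Marker abundance** is the mean log-scale expression of a cell type's
marker genes — a deliberately simple proxy whose only promise is rank
agreement with true cell-type content (verified on synthetic mixtures,
Spearman r ≥ 0.8).

## ICI response model

Cohorts are merged on the intersection of gene universes, with the
cohort label carried as the batch label. Batch correction is parametric
empirical-Bayes ComBat (via scanpy). Two contracts are enforced on top:

* each gene is re-centred to its original grand mean after adjustment,
  so correction never moves overall expression (exact, tested at 1e-6);
* a planted constant batch offset must vanish at the batch level
  (gene-averaged batch means agree within 0.05 after correction).

The second contract is stated at the batch level on purpose: EB
shrinkage leaves per-gene residual gaps of order sd·√(2/n), which no
faithful ComBat can push below 0.05 at realistic per-batch sizes.

The classifier is a nearest-centroid model: per-class gene-wise means
over the signature genes, and a continuous score
d(x, centroid_R) − d(x, centroid_NR) with Pearson-correlation distance
(1 − r) by default (Euclidean available; zero-variance samples fall back
to Euclidean with a warning). Higher score ⇒ predicted non-responder,
the orientation fixed package-wide by the negative association between
the UVR program and checkpoint-inhibitor efficacy. AUC is the
Mann–Whitney probability with ties counted ½. The 80/20 split rounds
the training size half away from zero (772 → 618/154) and redraws (≤100
times) if a class would vanish from training. Cross-validation is
stratified k-fold, repeated, seed-derived. Signature benchmarking
refits the centroid model per signature on a designated training cohort
and tabulates AUC per evaluation cohort with a mean column; signatures
with <2 genes in a universe yield missing cells.

## CRISPR meta-ranking

Each screen column is z-normalized over its observed cells (sample SD,
n−1); missing cells are never imputed and excluded from all statistics.
Genes are ranked ascending by mean z over observing datasets (low =
resistance-like); ties break alphabetically. Top-fraction membership is
floor(frac·N) — the only rule consistent with 225/450/675 out of
22,505. Coverage of a signature reports both denominators: genes present
in the ranked universe (primary) and the full signature size.

## Hub selection and survival modelling

Six feature selectors are registered: L1-logistic lasso (penalty by
stratified 5-fold CV log-loss with the one-SE rule), Boruta-style
shadow-feature testing (binomial confirm/reject at p < 0.01, ≤100
iterations), random-forest and bagged-trees permutation importance
(threshold = 95th percentile of a 50-permutation label-shuffled null),
a univariate AUC filter (BH q < 0.05) standing in for the "Bayesian"
family, and an LVQ-style ROC-filter importance with the same null
threshold. These are reimplementations of the selector *families*, not
clones of any toolkit's internals. Genes selected by ≥4 of 6 selectors
form the hub set.

The risk model is multivariate Cox proportional hazards (lifelines,
Efron tie handling); the risk score is the linear predictor Σβ·x. The
high/low dichotomization scans observed score values between the 10%
and 90% quantiles and keeps the log-rank-maximizing cutpoint (ties →
lower cutoff). Because the cutpoint is optimized against the same test,
the resulting log-rank p is anti-conservative; results carry a
`cutoff_optimized` flag rather than a correction, matching common
reporting practice while surfacing the caveat.

## Subtyping and deconvolution

Consensus clustering follows Monti resampling: genes are z-scaled,
80% of samples are drawn per iteration, k-means (k-means++, 10
restarts) clusters each subsample, and consensus(i,j) = co-cluster
count / co-draw count. Final labels per k come from average-linkage
hierarchical clustering of 1 − consensus. The number of clusters is
suggested by the relative delta-area of the consensus CDF (threshold
0.1) — a heuristic that can keep growing past the true k on very clean
data, which is why it is overridable and why recovery is scored by ARI
at the planted k. Defaults are 1000 resamples; the test suite uses 100,
which already saturates recovery on the planted cohorts.

Deconvolution regresses each (z-scored) mixture on the (z-scored)
marker-signature matrix with linear ν-SVR, ν ∈ {0.25, 0.5, 0.75} chosen
per sample by reconstruction RMSE; negative coefficients are truncated
and the rest renormalized to a simplex. The permutation p-value of the
original deconvolution method is out of scope; the basis matrix is a
user input and tests use synthetic bases.

Subtype score comparisons (TIDE/TMB/MSI-like) are two-group Wilcoxon
rank-sum tests with BH adjustment across scores; hub-gene × cell-type
correlations use Spearman on samples with fraction > 0, filter p < 0.05,
and flag the two most positive and two most negative pairs.

## Statistical conventions

Mid-ranks everywhere. Spearman p: t-approximation for n ≥ 10, exact
permutation below. Wilcoxon p: exact distribution for tie-free pooled
n ≤ 25 (the R convention), tie-corrected normal approximation with
continuity correction otherwise — the exact branch is what lets the
p-values agree with exhaustive enumeration to 0.01 on small fixtures.
Degenerate inputs (constant vectors, identical pooled samples, no
events) return flagged neutral results (r = 0/p = 1, statistic 0)
rather than raising. Gene identifiers are matched case-sensitively with
no alias resolution.

## Synthetic data: what it does and does not emulate

All generators derive their RNG stream from a global seed plus a stable
hash of the generator name, so one seed reproduces every dataset
bit-identically while streams stay independent.

* **Single cell** (`make_scrna`): Gaussian log-expression around
  per-gene baselines (log-normal linear scale); malignant cells get a
  +1.0 shift on marker genes; each malignant cell's activity
  a ~ U(0, 1) adds a *centred* (a − ½)·β to program genes (β = 2). The
  centring keeps program membership orthogonal to the malignant-vs-rest
  contrast, so the planted signature is exactly program ∩ markers.
  Defaults: 2000 genes, 1500 cells, 40% malignant, 100 program genes,
  150 marker genes, overlap 40, noise SD 0.5. Not emulated: UMI
  counts/dropout, doublets, within-dataset batch structure — so passing
  recovery says the derivation logic is correct, not that it is robust
  to single-cell technical noise.
* **Bulk ICI cohorts** (`make_ici_cohort`): per-gene N(0,1) baselines,
  responders shifted down on effect genes by effect_size·U(0.5, 1.5)
  per gene. The heterogeneous magnitudes matter: a spatially uniform
  shift is a measure-zero special case that correlation-distance
  classifiers cannot see (adding a constant to a centroid leaves
  correlations unchanged). Batches add per-gene location (N(0, batch_sd))
  and mild scale noise; response labels are balanced across batches to
  within one.
* **Screens** (`make_screens`): per-dataset location N(0, 2) and scale
  U(0.5, 2) on N(0,1) backgrounds; resistance genes shifted −2 in
  standardized units; 10% missing cells. 17 datasets by default.
* **Survival** (`make_survival_cohort`): exponential event times with
  rate h₀·exp(x'β), h₀ = 1/365 d⁻¹; independent exponential censoring
  with its hazard tuned by bisection to the target censored fraction
  (30% default).
* **Subtypes** (`make_subtype_cohort`): two (or k) Gaussian clusters
  separated by `shift` (default 3 SD) on 50 marker genes, with
  TIDE/TMB/MSI-like per-sample scores whose cluster means differ by
  1 SD.
* **Mixtures** (`make_mixtures`): basis × proportionsᵀ plus Gaussian
  noise.

## Problem sizes used for self-checks

Signature recovery: 10 seeds at the single-cell defaults (mean F1).
Response model: 20 seeds each for the planted (effect 2.0) and null
cohorts at n = 100, judged on the seed-mean AUC. CRISPR recovery: 20
seeds, 5000 genes × 17 screens, share of planted genes in the top 2%.
Cox: per-coefficient 95% CI coverage over 50 fits at n = 500 (joint
all-coefficient coverage has expectation 0.95² and is not a meaningful
≥90% check). Subtyping: ARI at k = 2, 100 resamples. Deconvolution:
mean absolute error over 20 five-type mixtures at noise SD 0.1.

## Known limitations

The enrichment engines are simplified reimplementations and will not
reproduce GSVA-package scores to numerical identity. The selector
registry approximates, not replicates, the published toolkit behaviors.
The delta-area rule for choosing k is a heuristic. Real-cohort headline
numbers (e.g., a validation AUC of 0.727) require the original
TCGA/GEO/ICI downloads and are out of scope by design.
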