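# Methods

## Stability clustering

### Dendrogram

Cells are compared by Euclidean distance over a user-chosen gene set in the
original expression space; no dimensionality reduction is applied. The
dendrogram uses Wishart's formulation of Ward's method: the Lance–Williams
recurrence

d(ij,k) = [(n_i + n_k) d(i,k) + (n_j + n_k) d(j,k) − n_k d(i,j)] / (n_i + n_j + n_k)

applied to *squared* Euclidean distances, with merge heights reported on
that squared scale. Only relative heights matter for cutting, so the choice
of scale is a convention; the squared scale makes the recurrence exact and
the heights monotone non-decreasing. The implementation delegates the
agglomeration to `scipy.cluster.hierarchy.linkage(method="ward")` — whose
update is exactly this recurrence followed by a square root — and squares
the returned heights; the test suite checks it merge-by-merge against a
naive O(n³) recurrence implementation on all small random instances.

### Window scan

The tree is cut at heights h_w = (w / W) · h_max for w = 1..W (default
W = 40 windows). A cut at height h groups leaves connected by merges of
height strictly below h, so window boundaries are unambiguous when merge
heights coincide with grid points; window 1 is the highest resolution and
the last window, cut at h_max itself, yields the top split. The
**stability** of a partition is the length of the longest consecutive
window run that reproduces it exactly, divided by W. The selected window is
the maximal-stability partition, with ties broken toward more clusters
(higher resolution, so that small subpopulations masked by large ones can
surface) and then toward the earlier window. Two trivial partitions are
excluded from selection as long as anything else persists: the single
all-cells cluster and the all-singletons partition in which nothing has
merged. Without the second exclusion, data with no cluster structure would
be "resolved" at the bottom grid edge — the nothing-merged run is long on
homogeneous data and the more-clusters tie-break would always pick it; with
it, unstructured data votes its way down to k ≈ 2 with visibly low
stability, which is the honest answer.

### Bagging

The full-data distance matrix is computed once and stored. Each of
`n_bags` (default 100) bagging runs draws ⌈proportion · n⌉ cells (default
proportion 0.8) and re-clusters the induced sub-matrix, obtained purely by
integer indexing — entries are bit-identical to the parent matrix, which is
both the speed trick (no distance recomputation) and a tested invariant.
The run records the optimal cluster count of the subsampled tree; the modal
count over bags wins the vote (ties to the smaller count), and the final
partition is the most stable window of the *original* tree with the voted
count. If no window has that count, the scan optimum is returned and
flagged (`fallback_used`).

Subsampling is **without replacement** by default. Sampling with
replacement and retaining duplicates — exposed as `replace=True` — makes a
duplicated cell an inflated-weight point under Ward: clumps of duplicates
resist merging, push otherwise-early merges toward the top of the tree and
fragment the window bands, and on the reference three-cluster fixture the
per-bag vote then disperses (roughly a third of bags recover the planted
count, the rest land on 2 or on near-singleton resolutions). Plain
subsampling at the same proportion concentrates 95+ of 100 bags on the
planted count, which is the behaviour the bagging diagnostic is designed to
show; both schemes share the bit-identity contract.

All randomness descends from one caller seed through
`numpy.random.SeedSequence.spawn`, so a fixed seed yields bit-identical
results.

## Transition scoring

### Model

For a source cluster C in its dataset, the response is y_i = 1(cell i ∈ C)
and the predictors are the expression values of the chosen genes. The
classifier minimizes the L1-penalized binomial negative log-likelihood
(1/N) Σ ℓ(y_i, β0 + x_i·β) + λ‖β‖₁ with the intercept unpenalized. Genes
are centered and scaled to unit variance at fit time (constant genes are
dropped with a warning); coefficients are reported back on the original
expression scale. An `l1_ratio` parameter mixes in a ridge term (elastic
net); the default 1.0 is the pure LASSO. A λ path of `n_lambda` values
(default 100) runs log-spaced from λ_max = max_j |x_jᵀ(y − ȳ)|/N — the
smallest penalty at which every coefficient is zero — down to 0.01·λ_max.
Each candidate is fitted with liblinear (C = 1/(Nλ), intercept_scaling 100
so the intercept penalty is negligible; saga for l1_ratio < 1), and the λ
minimizing stratified K-fold cross-validated misclassification error
(default K = 10, reduced with a warning when the smaller class is smaller,
minimum 3) is selected, with ties resolved to the larger λ — the sparser
model. The model is then refit on all training data at that λ.

The fitted model assigns any cell x the posterior
σ(β0 + x·β) ∈ (0, 1). The transition score from source to target is the
exact fraction of target cells with posterior strictly above the threshold
(default 0.5; the printed score is that fraction, a proportion in [0, 1]).
Scoring a target in another dataset presumes `align_gene_universe` was
applied so both matrices share the model's gene columns. The direction
convention: the model is trained one-vs-rest on the *source* cluster in the
source dataset and applied to *target*-cluster cells; a flag-free way to
get the opposite convention is to swap the populations.

Genes with non-zero coefficients, ranked by |coefficient| with sign
retained, are reported as the transition's driver genes.

### Uncertainty and control

The bootstrap mode refits the whole procedure — CV penalty selection
included — on ⌈0.8 n⌉ source cells drawn without replacement (redrawn if a
class vanishes) and rescores the full target set, reporting all run scores,
their mean (the headline score) and standard deviation. Whether to re-run
penalty selection per bootstrap or freeze the full-data λ is a genuine
choice; re-running propagates selection uncertainty into the score spread
and is the implemented behaviour.

The LDA control fits a two-class linear discriminant on the full
(unshrunken) gene set: pooled within-class covariance, ridge-regularized by
1e-6 · trace/p so it is invertible when genes outnumber cells, empirical
class priors, posterior by the usual discriminant softmax. It thresholds
target cells exactly like the penalized model, giving a full-model /
shrunken-model comparison; both models' training misclassification rates
are available side by side (`train_error`).

The pairwise matrix scores every ordered non-self pair within one
population, or every population-1 source against every population-2 target
in two-population mode (`include_reverse` adds the opposite direction);
clusters below `min_cells` (default 10) are skipped with a warning.

## Synthetic data

The simulator emulates deeply sequenced full-length scRNA-seq counts on a
deliberately small gene universe. Per-gene baseline means are log-normal,
exp(N(base_mean_log_mu, base_mean_log_sigma)) with defaults (3.0, 0.5) —
about 20 counts per gene per cell, so ~4000 counts per 200-gene cell.
Counts are negative-binomial with mean μ and size θ (`dispersion`,
default 10): variance μ + μ²/θ. Conventions differ between tools, so
explicitly: larger θ means closer to Poisson. Each cluster's
`n_markers_per_cluster` (default 20) markers — disjoint across clusters —
have their mean multiplied by `fold_change` (default 4) in that cluster;
markers are strictly up-regulated. These defaults were fixed so that the
default fold change of 4 produces *well-separated* clusters (exact
recovery by the stability clusterer), making `fold_change` the
separability dial: as it approaches 1 there is no recoverable structure
and the clusterer votes its way to k ≈ 2 at low stability. At shallower
depth or stronger overdispersion the same fold change gives partially
overlapping clusters, which is useful for robustness exploration but is
not the reference regime.

The two-dataset mode plants cluster A (with a program) and cluster B (pure
baseline) in dataset 1, and A′ and C in dataset 2, where A′ retains a
fraction `sharing_rho` of A's markers and C has its own disjoint program.
B is left programless deliberately: were B given a program, the A-vs-B
classifier would legitimately learn "B markers absent" as evidence for A,
and fully baseline cells (A′ at ρ = 0) would score ≈ 0.3–0.4 rather than
≈ 0 — the classifier must be forced to rely on positive A-marker evidence
for ρ to behave as the ground-truth relatedness dial. With this design the
mean bootstrap score A→A′ rises monotonically from ≈ 0 at ρ = 0 to ≈ 1 at
ρ = 1, and partial sharing (ρ ≈ 0.25) yields strong directional asymmetry:
A′'s classifier needs only the retained markers, which A-cells all carry
(score A′→A ≈ 1), while A's classifier expects the full program that
A′-cells mostly lack (score A→A′ ≈ 0).

What the simulator does *not* model — dropout beyond NB zeros, batch
effects, library-size gradients, down-regulated markers, doublets — bounds
what passing tests show: recovery results certify the algorithms under
clean NB cluster structure, not robustness to real-data artefacts.

## Pipeline conventions and numerics

- Gene selection by variance runs on the matrix *as loaded* (raw counts
  unless declared normalized), before log-CPM: on log scale the variance
  ranking is dominated by low-mean noise and anti-selects markers.
- log-CPM is a deliberately plain default (rows scaled to 1e6, then
  log2(x+1)); users with their own normalization should load data with
  `normalized=True`, which skips it.
- Variance ties in gene selection break lexicographically on gene id;
  window ties toward more clusters; vote ties toward fewer clusters;
  λ ties toward the larger penalty. All deterministic.
- Degenerate inputs: cells with zero total count fail normalization with
  the cell named; an all-identical bag returns k = 1 with a warning;
  single-class training sets and empty target sets are errors.
- Problem sizes in the test and acceptance runs (300-cell mixed
  populations, 240-cell dataset pairs, 60-gene selections, 40–50-point λ
  grids, 6–8 bootstrap refits) are the package's reference desk-scale
  conditions; every reported number is recomputed from a seed at run time.

## Known limitations

- The window grid is linear in squared-scale height; very unbalanced trees
  concentrate informative resolutions into few windows, and the default 40
  windows can be too coarse above ~10 true clusters.
- The transition score is a thresholded proportion: it says which fraction
  of target cells a linear classifier places in the source class, not a
  dynamical probability; time ordering must come from the experiment.
- One-vs-rest training with two clusters makes "rest" a single cluster, so
  negative evidence is concentrated; with many clusters the score is less
  sensitive to any single other cluster's program.
- No class weighting is applied for imbalanced one-vs-rest training by
  default (`class_weight` is exposed).
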