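# Methods

## The integration problem

Two single-cell datasets measure different molecular layers on *different*
cells: a gene-expression matrix `X1` (n1 cells × p1 genes) and a second
modality `X2` that has already been brought into a linkable feature space —
either a gene-activity matrix computed from scATAC-seq peaks by an external
tool (ArchR, Signac, cisTopic, …) or a surface-protein matrix with a known
gene↔protein mapping. Neither the cell correspondence nor a joint embedding
is observed. `bialign` learns cell embeddings `Z_v ∈ R^{n_v×d}` and feature
embeddings `Y_v ∈ R^{d×p_v}` for both modalities simultaneously, so that
cells of the same type mix across modalities while cell types stay separated,
and so that the feature embeddings remain usable for regulatory downstream
analysis.

## Model

**Preprocessing (per modality).** Count-like matrices are total-count
normalized to 10,000 per cell, log1p-transformed, z-scored per feature and
truncated to ±10; continuous matrices skip the count-specific steps and are
z-scored and truncated directly. Highly variable features are selected by
the binned normalized-dispersion statistic (scanpy's `seurat` flavor) for
count data and by plain variance for continuous data, with ties broken by
lexical feature id; protein panels keep every measured feature because only
~10²  proteins exist. A rank-q PCA (default q = 100, shrunk to matrix size)
of the processed HVG matrix supplies the encoder inputs: cell scores for the
cell encoder and feature loadings for the feature encoder. PCA is *only* an
encoder input compression; anchor construction never uses it.

**Shared feature space and anchors.** For gene-indexed modality pairs the
shared space is the union of the two HVG lists restricted to features present
in both matrices; for RNA+protein it is exactly the mapped gene–protein
pairs. Cell anchors are mutual nearest neighbors under cosine distance in
this shared space: (i, j) is an anchor iff i is among the k nearest
modality-1 cells of cell j and vice versa, with ties broken toward the
smaller index so the set is deterministic. Feature pairs are one-to-one:
identity matches on shared gene ids, or the gene↔protein mapping with every
ambiguous (many-to-one) entry dropped entirely.

**Architecture.** Each modality has a cell encoder and a feature encoder:
two hidden blocks of linear → batch-normalization → LeakyReLU(0.2) →
dropout(0.2), then a linear head to the latent dimension d. The decoder is a
low-rank bilinear map with per-feature learnable scale and bias,

    X̂_v = softplus(scale_v) · (Z_v Y_v) + bias_v ,

reconstructing the clipped z-scored HVG matrix (per-feature scale/bias
strictly generalize the scalar reading and suit standardized targets).

**Losses.** The total objective is

    L = γ_a‖X1−X̂1‖² + γ_b‖X2−X̂2‖² + α·L_cell + β·L_feat ,

with both contrastive terms of InfoNCE form on cosine similarity at
temperature τ = 0.5: for a positive pair, −log of the softmax weight of the
positive among the positive plus the negatives. The denominator includes the
positive term (the standard InfoNCE family convention), which guarantees
nonnegativity and makes the equal-logit two-candidate case exactly ln 2.
Negatives are all other cross-modal samples in the current mini-batch, and
each contrastive loss is computed in both directions (1→2 and 2→1) and
averaged, removing the arbitrary modality ordering. During optimization the
reconstruction term uses per-batch mean squared error so its magnitude is
batch-size-independent; the standalone `loss_reconstruction` operation
returns the literal weighted squared-Frobenius sum.

**Training.** All parameters are trained by Adam (lr 1e-4, L2 weight decay
5e-5) with mini-batches of 256 cells and 256 features, for up to 1000 epochs
with early stopping (patience 30 epochs on an exponentially smoothed total
loss, relative tolerance 1e-4 — a concrete rule chosen where only "early
stopping" is specified). Cell batches put sampled anchor pairs at aligned
positions and fill the rest with random cells so non-anchored cells still
receive reconstruction gradients; feature batches cycle through a shuffled
queue of all positive feature pairs each epoch so sparse correspondences
(e.g. ~10² gene–protein pairs) are never starved. Final embeddings are
extracted in evaluation mode (dropout off, batchnorm running statistics), so
they are deterministic given the seed. Because the contrastive objective is
angular, cell embeddings are L2-normalized on output by default
(`normalize_embeddings`); this places them on the unit sphere, the geometry
in which the Euclidean-distance evaluation metrics see the alignment the
objective actually optimized. Defaults α = β = 1e4, γ_a = γ_b = 1,
τ_c = τ_f = 0.5, d = 50, hidden widths (512, 256).

The networks, backpropagation and Adam are implemented in-package on a small
reverse-mode autodiff engine over numpy arrays (`bialign.nn`); every
gradient is validated against central finite differences (1e-4 relative) in
the test suite.

**Default k for anchors.** 100 for RNA+ATAC and 500 for RNA+protein, which
match the regimes where integration quality is flat for datasets of 10³–10⁴
cells; for small datasets k should be scaled to roughly 0.1–5 % of the
smaller modality (the benchmark studies use k = 25 for 500-cell modalities).

## Evaluation metrics

Omics mixing = mean of GC, SAS and ASW-O; cell-type conservation = mean of
MAP, ASW and NMI; plus label-transfer accuracy (5-NN classifier trained on
the larger modality) and, for paired data, FOSCTTM (fraction of
opposite-modality cells strictly closer than the true match, Euclidean,
averaged over both directions; ties count as not closer).

Unstated details resolved as follows: neighbor counts default to k = 15
(GC), 10 (SAS), 30 (MAP); SAS's x̄ is the same-omics neighbor *count* among
k (this makes the stated normalization hit exactly 0 and 1 at the two
limits), each omics layer is subsampled to the smallest layer's size, with
3 seeded repeats averaged; NMI clusters the joint embedding with seeded
k-means at k = number of true types; ASW enters the conservation aggregate
on its raw [−1, 1] scale. A cell type present in only one modality is
excluded from ASW-O with a warning; a type with a single cell contributes 1
to GC.

## Downstream analyses

Gene modules: cosine-similarity kNN gene–gene graph (k = 5,
union-symmetrized, similarity weights) partitioned by greedy modularity
maximization (networkx). Module enrichment: one-sided (upper-tail)
hypergeometric test of regulator-target overlap against the universe of
embedded genes, BH-adjusted across all (module, regulator) tests; regulators
significant at adjusted p < 0.05 in ≥ 1 module are retained. The regulator
table is user-supplied (regulator, target, optional confidence letter, so
cumulative A/AB/ABC stratifications are expressible). Marker genes: the
gene–cell cosine-similarity matrix aggregated per cell type — the type-level
statistic is the mean over that type's cells (max and rank-sum are exposed
as alternatives since only "highest similarity scores" per type is
prescribed) — and the top 50 genes per type selected. Cell-type interaction
network: cosine kNN cell graph (k = 100), edge weights (clipped at 0) summed
between type pairs, row-normalized, symmetrized, and upper-triangle entries
below 0.005 masked.

## Synthetic data

The generator draws cell-type centroids in a true latent space (centroids
rescaled so their minimum pairwise distance equals `type_separation`,
making separability a single knob), adds isotropic latent noise per cell,
and observes each modality through its own loading matrix plus Gaussian
observation noise — or, for `count_model="negative_binomial"`, through
exponentiated latent means with fixed dispersion 0.5, emulating
overdispersed count data. The loading columns of shared features are
identical across modalities, so feature correspondences carry real signal. A
fraction `pairing_ratio` of cells re-uses the same latent vectors in both
modalities and is recorded as ground-truth pairs. `split_paired_dataset`
reproduces the pairing-ratio experimental design: retain a fraction p of
pairs in both modalities and split the rest evenly, each cell kept in
exactly one modality.

Default conditions: 500 cells per modality, 4 balanced types, 80 shared +
20 private features per modality, latent dimension 10, noise SD 0.5,
centroid separation 6 — clearly clustered but noisy data, the regime the
method is designed for. What the generator does *not* emulate: realistic
chromatin-peak structure, batch effects beyond modality-specific loadings,
nonlinear feature responses, or empty droplets. Passing tests therefore
demonstrate correct mechanics and recoverable alignment under linear-Gaussian
modality maps, not performance on real tissue atlases.

## Benchmark studies (`bialign.benchmarks`)

The studies fix one scaled-down configuration for the 500–800-cell regime:
latent dimension 16, hidden widths (64, 32), learning rate 1e-3, k_mnn = 25
(~5 % of a 500-cell modality), 500 training epochs (250 for the multi-run
ablation and pairing-ratio studies), n_hvg = 100, q = 30. The higher
learning rate and smaller network simply rescale the optimization to the
small problem; library defaults remain the published-scale settings.

* **Parameter recovery** (pairing ratio 0): label-transfer accuracy,
  omics mixing, cell-type conservation, and the same metrics for the
  unintegrated per-modality PCA baseline.
* **Paired alignment**: fully paired data, true correspondences used as
  anchors, FOSCTTM of the result.
* **Ablation**: α = 0 vs β = 0 on five seeds; the cell-level term is
  expected to matter more for mixing than the feature-level term.
* **Pairing-ratio robustness**: one fully paired dataset split at
  p ∈ {0, 0.1, 0.3, 0.5, 0.8}; the spread of LTA across ratios.

## Numerical choices and limitations

* All randomness flows from explicit `numpy.random.Generator` seeds; equal
  seeds give bit-identical loss traces and embeddings on one machine.
* MNN search is exact (full cosine similarity matrix); practical up to
  ~2×10⁴ cells per modality, above which memory grows quadratically.
* Distance/similarity ties break toward the smaller index everywhere.
* PCA fixes each component's sign by making its largest-magnitude loading
  positive, for cross-platform reproducibility.
* Degenerate inputs fail loudly: zero-total cells, all-zero rows under
  cosine, constant matrices in HVG selection, empty anchor or feature-pair
  sets, non-finite losses during training.
* The decoder enum exposes only the bilinear softplus variant; alternative
  MLP decoders are a configuration hook, not implemented.
* Two-modality integration only; many-to-many feature links and >2
  modalities are out of scope.
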