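# Methods

This note documents the model, the synthetic-tissue generator, and the
numerical and design choices behind `heist`. It is the place to look
when a default needs justification.

## The hierarchical graph

A tissue is represented at two levels. The **spatial cell graph**
connects cells whose Voronoi regions touch; we compute it as the
Delaunay triangulation (the exact dual of Voronoi adjacency) and prune
edges above the 0.99 quantile of edge length, which removes the long
convex-hull chords that Delaunay adds at tissue borders but Voronoi
adjacency semantics do not intend. On point sets small enough to check
exhaustively, the unpruned graph equals a brute-force half-plane
Voronoi-adjacency oracle exactly (this is a test, not an assumption).
Duplicate coordinates are jittered by a seeded 1e-9 × bounding-box
diagonal perturbation because triangulation needs general position.

Each cell also carries a **gene co-expression network** shared by all
cells of its type. Preprocessing follows the standard single-cell
recipe: cells whose log1p total count deviates from the median by more
than 3 median absolute deviations are dropped; rows are scaled to the
median total and log1p-transformed; the genes with highest normalized
dispersion (variance/mean) are kept. Expression is then denoised by
diffusion: an adaptive-Gaussian kNN affinity over cells (bandwidth =
distance to the k-th neighbour, k = 15), symmetrized and balanced to a
**doubly stochastic** Markov operator by Sinkhorn iteration, applied
t = 3 times. The doubly stochastic convention is deliberate: it makes
per-gene column mass exactly conserved, so denoising redistributes
signal between cells but never creates or destroys it — a property the
test suite asserts to 1e-6. A purely row-stochastic operator conserves
neither row nor column mass.

Cell types come from provided annotations when available, otherwise
Leiden communities of a kNN expression graph. Classes with fewer than 3
cells are merged into the nearest class by centroid distance, because
the MI estimator below needs at least 3 samples.

**Mutual information.** Pairwise MI between denoised genes within one
type uses equal-frequency discretization into `B = min(16, ⌊√n⌋)` bins
and the plug-in entropy estimator, in nats. Identical values always
share a bin, so a constant gene has zero MI against everything by
construction rather than by special-casing. The plug-in estimator is
biased upward by roughly `(B−1)²/(2n)` for independent pairs (≈ 0.22
nats at n = 500, B = 16); we keep the plug-in form because the package's
oracle tests require exact identities (MI(p,p) = discretized marginal
entropy; symmetry to 1e-12), and thresholding is rank-based in the
default mode, where a uniform bias is harmless. The **adaptive
threshold** sets τ per cell type to the smallest value whose surviving
edges have mean degree ≤ 10; the constant-τ mode keeps pairs with
MI > τ directly.

## The encoder

Embeddings have width d = 64 with L = 2 layers and 4 attention heads.
Initialization is positional-encoding based:

* gene row (k, v): sinusoid of the *rank* of gene v's denoised
  expression within cell k (ties broken by gene index), plus the raw
  value added to coordinate 0;
* cell row k: concatenated sinusoids of min-max-normalized x and y
  (coordinate scale 4 — see below), plus the raw normalized coordinates
  added at positions 0 and d/2, plus the cell's raw denoised expression
  vector folded in modulo d.

Raw features are always added directly, never passed through a learned
map first. Two of these choices deserve justification because they are
the package's own:

* **Raw expression in the cell rows.** The cross-level update (below)
  passes gene-level information to a cell only through a scalar gate —
  the output is a scalar multiple of the cell's own value vector. A
  cell initialized from coordinates alone therefore has no channel wide
  enough to acquire a full expression signature, and measured cell-type
  recovery from embeddings stays near chance no matter how long the
  model trains, while the contrastive loss happily minimizes itself
  with position-local structure. Adding the expression vector directly
  to the cell row (folded modulo d when |V| > d) gives the spatial level
  the same raw material the gene level has.
* **Coordinate PE scale 4.** With the conventional scale for long token
  sequences, positional variance occupies most of the 64 dimensions and
  swamps expression variance in any distance-based analysis of the
  embeddings. Scale 4 over the unit square leaves position legible in a
  handful of dimensions.

Each layer applies an **intra-level step** — multi-head attention
restricted to graph neighbours plus self, then residual + layer norm +
feed-forward (post-norm) — separately on the spatial graph and on every
cell's gene graph. Gene sets are small, so the gene level runs as dense
masked attention batched over cells (one |V|×|V| mask per cell type);
the spatial level uses sparse edge-list attention. Output projections
are initialized at 1/10 the usual Glorot scale so every block starts
near the identity; without this, two rounds of neighbour averaging
erase most cell-specific signal before training begins.

The **cross-level step** uses the directional gate

    out_i = (⟨(H_to W_q)_i, (H_from W_k)_i⟩ / d) · (H_to W_v)_i

with the denominator d exactly as printed in the architecture this
package implements (not √d). Genes receive their parent cell's
embedding repeated |V| times; the cell receives the AGG of its gene
rows (mean by default; a learned softmax-weighted pooling is available
as `agg="diffpool"`). A residual connection around the gate is ON by
default — the literal gate can annihilate the state when the scalar is
near zero — and can be disabled to reproduce the literal equation.
Setting `cross_level=False` ablates the step entirely (used by the
acceptance suite's ablation).

## The decoder

A 3-layer graph isomorphism network (GIN, sum aggregation, 2-layer MLP
per block) runs on the cell graph from Zc with a 2-unit head for
coordinates, and on the gene graphs from Zg with a 1-unit head per gene
node for expression. GIN weights are initialized small (Glorot / 4)
because sum aggregation inflates magnitudes by roughly the mean degree
per layer; with conventional scales a fresh decoder predicts values
~10³ off the data scale and the masked-autoencoding loss starts in the
hundreds of thousands.

## Pretraining objectives

* **Contrastive.** Positive pairs are same-type cells within radius r
  (default: twice the median spatial edge length); negatives for cell i
  are different-type cells within r. Three InfoNCE terms (temperature
  0.1, cosine similarity): cell↔cell on Zc rows; gene↔gene between
  co-expression-adjacent gene pairs across a positive cell pair, with
  negatives drawn from non-adjacent genes of negative cells; cell↔gene
  between a cell row and the aggregated gene row z̄g of its positive
  partner, with negatives z̄g of negative cells. The printed forms are
  log-softmax ratios (≤ 0); they are implemented negated so that
  minimization pulls positives together. The gene↔gene sum over |V|² is
  subsampled: at most 128 cell pairs per batch and 64 gene pairs per
  cell pair, with one seeded non-adjacent negative per negative cell. A
  pair with no negatives contributes exactly 0.
* **Masked autoencoding.** Bernoulli masks hide 10% of cell coordinates
  and 30% of gene entries (zeros at the input). The loss is MSE
  restricted to masked entries: mean squared Euclidean error over
  masked cells for positions (min-max normalized to the unit square so
  both terms share a scale) plus the per-cell masked-entry MSE averaged
  over all cells.
* **Orthogonality.** ‖I − Z̃ᵀZ̃‖²_F for Zc and Zg with columns scaled to
  unit norm first; without the scaling the identity target is
  unattainable and the penalty grows with cell count. Weight λ = 1e-3.
* **Combination.** total = σ(γ)·contrastive + (1−σ(γ))·mae + λ·ortho
  with γ a trainable scalar initialized at 0, updated by the same
  optimizer as everything else.

Training uses Adam (lr 1e-3, global gradient-norm clip 5), spatial-patch
batches (seeded anchor + breadth-first neighbourhood, 512 cells; every
cell is covered each epoch), a 10% patch-level validation split, and
early stopping on validation loss (default patience 3 within at most 10
epochs). Validation passes run without building an autodiff tape.

## Synthetic tissues

The generator emulates exactly the structure the model assumes: cells
uniform in the unit square; **niches** as Voronoi regions of seeded
anchors, with anchors placed by best-candidate sampling so the regions
have comparable areas (as tissue regions do); **cell types** drawn from
a niche-dependent mixture (each niche favours one type, so composition
shifts without determinism); latent expression = type baseline (+2.5 on
each type's marker block) + module factors (per-cell N(0,1) factors ×
loading 0.6 on 10-gene blocks, two modules per type, giving
within-module correlation ≈ 0.8 ≫ cross-module ≈ 0.45) + niche offsets
(±0.8 on a random third of the genes, a fixed sign pattern per niche) +
N(0, 0.3) noise, passed through softplus to stay nonnegative;
**dropout** zeroes entries i.i.d. at rate 0.4.

Calibration was checked from the generator alone, without a model in
the loop: cell types are recoverable from clean expression at NMI ≈ 1.0
(the identifiability requirement), within-type niche labels are
recoverable from clean expression at NMI ≈ 0.5–1.0 per type, the
observed zero fraction matches dropout + clean zeros, and the module
correlation ordering holds. The generator intentionally omits
platform-specific noise, segmentation error, batch effects and 3-D
structure, so passing tests demonstrate correct mechanics and
recoverable planted structure — not performance on real assays.

Default sizes (1500 cells, 60 genes, 3 types, 3 niches) keep a full
pretrain–evaluate cycle to minutes on one CPU; the acceptance runs use
five training seeds on one fixed tissue.

## Evaluation protocols

* Clustering: Leiden or spectral/k-means on embeddings, scored by NMI.
  Cell-type recovery clusters all cells into 3 groups. Niche recovery
  is assessed *within one cell type*: the reference type is chosen
  model-free as the type whose planted niche substructure is clearest
  in clean generator expression, and that type's cells are clustered
  spectrally into as many groups as niches present — the same shape of
  analysis as inspecting sub-clusters of one chosen subpopulation.
* Annotation: 2-layer MLP head (64 hidden units) on frozen embeddings,
  stratified 80/20 split, macro-F1.
* Tissue classification: tissues represented by mean cell embeddings,
  MLP head, AUROC under leave-one-tissue-out cross-validation.
* Imputation: genes stratified into sparsity quartiles (rank-based, so
  the bins are always balanced); 10% of entries masked per bin;
  zero-shot runs the frozen encoder + decoder; fine-tuning retrains the
  decoder only (encoder frozen) on visible entries for 150 Adam steps
  (lr 3e-3) that cycle spatial patches of 512 cells — the decoder is
  graph-size independent, so patch-level steps converge at a fraction
  of the full-graph cost; Pearson r is pooled over masked entries. The
  per-gene-mean baseline predicts each gene's visible-entry mean.

## Numerical choices and degenerate inputs

float32 throughout the model; the autodiff core is a minimal
reverse-mode tape over numpy with sorted-segment sums for sparse
attention and a fused masked-softmax-attention primitive (only the
attention weights stay on the tape). Softmax subtractions use
per-segment maxima. Isolated nodes attend to themselves; a constant
gene has zero MI; an empty mask set yields a zero MAE term with a
warning; Pearson r of constant predictions is reported as 0 with a
warning; collinear or duplicate coordinates fail loudly or are
jittered as documented above. All randomness flows from explicit seeds;
identical inputs and seeds give bit-identical results on fixed
hardware.

## Known limitations

The gate-limited cell←gene channel is a property of the printed
cross-level equation; the raw-expression cell initialization compensates
at input time but does not widen the channel during message passing.
A consequence, visible in the test suite, is that ablating cross-level
message passing does **not** degrade within-type niche recovery on the
synthetic tissues: niche identity is carried by coordinates and by
niche-shifted expression, which the ablated model also receives at
input, and the full model — which optimizes the contrastive objective
substantially further — compresses within-type variance across niche
boundaries (same-type positive pairs straddle them). The corresponding
directional test states the expected ordering and currently fails; it
is left failing rather than weakened.
The MI estimator's upward bias is not corrected (see above). Training
at 22-million-cell scale, multi-GPU execution, batch-effect handling
across slices, 3-D coordinates and spot-level deconvolution are out of
scope.
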