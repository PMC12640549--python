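# Methods

## Model and assumptions

The pipeline assumes array-based spatial transcriptomics input: a
non-negative spots × genes count matrix with one 2-D coordinate per spot.
Spatial domains are modeled as latent structure that is simultaneously
(i) transcriptionally coherent, (ii) spatially contiguous, and (iii) —
when histology is supplied — morphologically coherent. Three mechanisms
encode these assumptions:

1. **Composite-weight augmentation** mixes neighbor expression into each
   spot before any model fitting. The spatial kNN indicator `W_s` restricts
   mixing to physical neighbors; the cosine term `W_g` and the normalized
   Euclidean morphology term `W_m` modulate each edge. The augmentation
   `X'_i = X_i + α Σ_j W_all[i,j] X_j` is applied once (not iterated) and is
   deliberately not row-normalized, so α is interpretable as an absolute
   neighbor-contribution scale.
2. **Graph-convolutional variational encoding** ties the latent posterior
   to the spatial graph: gated residual graph convolutions propagate
   information along tissue adjacency, and the inner-product decoder
   `p(A|Z) = sigmoid(ZZᵀ)` with its BCE term explicitly rewards latents
   whose geometry reproduces that adjacency.
3. **Denoising and attention** regularize the expression pathway: Gaussian
   corruption of the encoder output during training, and bias-free
   multi-head self-attention over spots at the input, mid-encoder, and
   pre-decoder stages, letting every spot's representation condition on the
   whole section.

Domain calls are Leiden clusters of the posterior means μ, never of a
sampled Z, so inference is deterministic given the seed.

### The expression weight is a dissimilarity

`W_g = 1 − cosine` weights *dissimilar* neighbors more, which then
up-weights dissimilar neighbors in the augmentation. That is the form
implemented by default; whether a similarity was intended is ambiguous, so
`expression_weight_mode="similarity"` provides the complement without
silently correcting the default behavior. In practice the spatial gate and
the downstream encoder dominate, and banded structure is recovered under
either mode.

### Reparameterization modes

Two forms are shipped. `standard` (default): `Z = μ + exp(½ log σ²)·θ` —
the form consistent with the Gaussian KL term
`−½ Σ(1 + log σ² − μ² − σ²)`. `paper_literal`: `Z = μ + log(σ²)·θ`, which
annihilates noise at σ² = 1 and flips sign for σ² < 1; it is provided as a
config switch for comparison, surfaced in logs, and never the default.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `k_neighbors` | 6 | spatial kNN degree; matches the hexagonal Visium neighborhood |
| `alpha` | 0.5 | neighbor-contribution scale in the augmentation (dimensionless); a moderate value between the identity (α=0) and full neighbor addition (α=1) |
| `target_sum` | 1e4 | per-spot library-size target before log1p (counts) |
| `n_hvg` | 3000 | highly-variable-gene cut, plain variance ranking |
| `pca_dim` (M) | 200 | post-augmentation PCA width; mid-range of the regime where performance is flat in dimensionality |
| `attention_heads` | (8, 4, 8) | input / mid-encoder / pre-decoder head counts; every stage dimension must divide by its head count |
| `dae_hidden_dims` | (128, 32) | denoising encoder widths; G = 32 |
| `graph_hidden_dims` | (64,) | gated graph trunk widths |
| `latent_dim` (R) | 32 | must equal G — the decoder consumes Z + Z_E elementwise |
| `noise_sigma` | 0.1 | corruption SD on Z_E during training (latent units) |
| `loss_weights` | (1.0, 0.01, 0.1) | (mw, kw, aw); chosen so no term dominates by >10× at initialization on the standard fixture |
| `learning_rate` | 1e-3 | Adam, full batch |
| `epochs` | 500 | default budget; the standard 900-spot fixture converges usefully by ~200 and can overfit the adjacency term well past that |
| `leiden_knn` | 15 | kNN graph degree on the latent for clustering |

All stochastic stages derive their seeds from one global seed by hashing
the stage name, so disabling one stage (e.g. an ablation) never shifts
another stage's random stream.

## Synthetic data generator

The simulator emulates the statistical structure the model assumes: spots
on an integer grid; spatially contiguous domains as near-equal horizontal
bands (cortical-layer-like geometry) or seeded Voronoi blobs; counts drawn
negative-binomially (gamma–Poisson, `var = m + m²/θ`, dispersion θ = 10
over baseline mean 5) with each domain's marker genes elevated by
`2^log2FC` (default four-fold); independent Bernoulli dropout (default
20%) applied after sampling; and optional morphology features as
per-domain Gaussian mean vectors plus isotropic noise.

It deliberately does **not** emulate: spatially varying library size or
capture efficiency, platform-specific noise spectra (Stereo-seq binning,
MERFISH probe panels), gene–gene correlation beyond the domain block
structure, gradual boundary transitions, or batch effects. Passing tests
on this generator therefore demonstrate that the pipeline recovers clean,
contiguous, marker-driven domains under overdispersed counts and dropout —
not that it resolves the subtler failure modes of real sections.

The standard fixture used across the heavier tests is 900 spots (30 × 30),
200 genes, 3 bands, log2FC = 2, dropout 0.2, with 200 training epochs and
three seeds — sizes chosen so the whole suite stays comfortable on a single
CPU while remaining in the regime where the method demonstrably works;
recovery degrades on much smaller grids where boundary spots dominate.

## Numerical choices

* **Variational head initialization.** The μ and log σ² heads are
  initialized at 0.1 × Glorot. The gated graph convolution has no degree
  normalization (faithful to the cited layer), so activations grow with
  node degree through the trunk; full-gain heads can put log σ² in the
  hundreds at initialization and overflow `exp` in float32.
* **log σ² clamp.** The forward pass clamps log σ² to [−10, 10] before
  reparameterization and the KL (gradient is zero outside the interval).
* **BCE.** Probabilities are clipped to [1e−7, 1 − 1e−7] before logs. The
  positive class is re-weighted by #non-edges/#edges. The evaluation
  support is all N² off-diagonal pairs for N ≤ 2000; beyond that, all edges
  plus an equal-size seeded sample of non-edges.
* **kNN ties** break toward the lower spot index in every construction
  method, so KDTree, BallTree, and brute-force agree exactly, including on
  duplicate coordinates.
* **PCA signs** are fixed so each component's largest-magnitude loading is
  positive; scores are therefore reproducible bit-for-bit.
* **`max(d)` in the morphology weight** is taken over the kNN support
  actually weighted, not all N² pairs — only supported entries survive the
  `W_s` product, and this keeps the cost O(Nk). All supported distances
  zero is handled as weight 1 everywhere (logged).
* **Degenerate inputs.** Spots with zero total count are left unscaled
  (not dropped) to keep indexing aligned with coordinates; a single
  cluster makes SC/DBI/CH not-computable and returns NaN markers rather
  than raising; zero-norm expression vectors get dissimilarity 1.
* **Leiden** runs its move phase to convergence (`n_iterations=-1`) —
  markedly cleaner partitions than a fixed small iteration count — under
  the modularity objective (constant Potts available). The target-count
  search bisects resolution in [0.05, 3.0] (≤ 30 iterations), returning
  the closest achieved count with ties toward the lower resolution.
* **Precision.** The network trains in float32 by default (configurable);
  the attention stages dominate memory at N × N per head, and the backward
  pass frees intermediate buffers as it consumes them.

## Design choices where the design was open

* Attention stages are pure transforms — no residual connections around
  them. Placement: on the N × M input, between the first and second
  denoising-encoder layers, and on (Z + Z_E) before the decoder stack.
* The denoising decoder is untied from the encoder (independent weights),
  mirrors the encoder widths in reverse, and reconstructs the
  *pre-attention* PCA matrix.
* The augmentation uses the asymmetric kNN weights exactly as defined; the
  adjacency fed to the graph encoder and the BCE target is the symmetrized
  (logical OR) version, since graph convolution and the reconstruction
  target assume an undirected graph. No self-loops anywhere: the gated
  layer has an explicit self term, and the diagonal is excluded from the
  BCE support.
* Training is full batch: the adjacency BCE couples all spots, and
  mini-batching would bias the pair support.
* Morphology is strictly optional (the composite weight drops `W_m`), and
  the embedder is an injectable contract. The packaged embedder —
  a 256-bin grayscale histogram followed by a fixed seeded random
  projection to 1000 features — is deterministic and weight-free; a
  pretrained vision backbone can be plugged in by passing any callable
  mapping a patch stack to an (N, F) matrix.

## Limitations

* The included histogram embedder captures coarse intensity structure
  only; it is a contract-satisfying stand-in, not a learned feature
  extractor.
* Full-batch training with dense N × N attention bounds practical section
  size on one CPU to a few thousand spots; there is no mini-batch or
  neighbor-sampling path.
* The resolution bisection assumes domain count is monotone in resolution,
  which Leiden only satisfies approximately; the closest achieved count is
  returned with a warning when the target cannot be bracketed.
* No batch integration across sections, no H5 Visium container input, and
  no image registration between resolution levels.
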