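# vargg

Spatial-domain identification for spatial transcriptomics: a pipeline that
fuses gene expression, spatial location, and (optionally) histology-derived
morphology into a latent representation via an attention-enhanced
variational graph autoencoder, then calls spatially coherent tissue domains
with Leiden clustering.

Spatial transcriptomics platforms (10x Visium and similar array-based
assays) measure a spots × genes count matrix together with each spot's 2-D
tissue position. The analysis target here is the *spatial domain*: a
contiguous tissue region with coherent expression and morphology — cortical
layers, tumor niches, hippocampal subfields. Clustering expression alone
ignores where spots sit; this package is for analysts who want domain calls
that respect both molecular and spatial structure, plus the standard
agreement/quality metrics to evaluate them.

## The model

**Neighborhood-weighted augmentation.** A kNN indicator over spot
coordinates defines the spatial weight

```
W_s[i,j] = 1  if j is one of the k nearest neighbors of i, else 0
```

Expression weights are cosine dissimilarity, `W_g[i,j] = 1 − X_i·X_j /
(‖X_i‖‖X_j‖)`, and morphology weights (when histology features F are
available) are normalized Euclidean distances, `W_m[i,j] = 1 − d_ij /
max(d)`. Their elementwise product `W_all = W_s × W_g × W_m` (the `W_m`
factor is dropped without histology) gates how much neighbor expression is
added to each spot:

```
X'_i = X_i + α · Σ_j W_all[i,j] · X_j
```

The augmented matrix is PCA-reduced to M dimensions (default 200).

**Attention-enhanced denoising + variational graph autoencoding.**
Bias-free multi-head self-attention over spots (`softmax(QKᵀ/√d_k)V` per
head, heads concatenated and projected) is applied to the input matrix
(8 heads), inside the denoising encoder (4 heads), and before the decoder
(8 heads). The denoising encoder maps the N × M matrix to `Z_E ∈ R^{N×G}`;
training corrupts it with Gaussian noise, `H⁰ = Z_E + ε, ε ~ N(0, σ²)`. A
stack of gated residual graph convolutions over the symmetrized spatial
adjacency A,

```
h'_i = ELU( W₁h_i + Σ_{j∈N(i)} σ(W₃h_i + W₄h_j) ⊙ W₂h_j )
```

feeds two parallel heads producing the posterior mean μ and log-variance
log σ². The latent sample `Z = μ + exp(½ log σ²)·θ, θ ~ N(0, I)` decodes
two ways: edge probabilities `p(A|Z) = sigmoid(ZZᵀ)` and the expression
reconstruction `X̂ = Decoder(Z + Z_E)`. Training minimizes

```
L = mw·MSE(X̂, X) + kw·KL(μ, log σ²) + aw·BCE(p(A|Z), A)
```

full-batch with Adam. Domains are Leiden clusters of the converged μ, at a
fixed resolution or bisected to a target domain count. Evaluation provides
chance-adjusted Rand index (ARI) and normalized mutual information (NMI)
against ground truth, plus silhouette (SC), Davies–Bouldin (DBI), and
Calinski–Harabasz (CH) internal indices.

The networks run on a small NumPy reverse-mode autodiff engine included in
the package (`vargg.autodiff`) — no GPU or deep-learning framework needed;
everything is seeded and bit-reproducible on CPU.

## Worked example

```sh
python examples/simulate_and_cluster.py
```

simulates a 30 × 30 grid (900 spots, 200 genes) with three banded domains —
each domain over-expressing its own 10 marker genes four-fold over a
negative-binomial baseline, with 20% dropout — and runs the full pipeline:

```
simulated 900 spots x 200 genes, 3 band domains
found 3 domains at resolution 0.234
   ARI: 0.935
   NMI: 0.904
    SC: 0.216
   DBI: 1.776
    CH: 196.120
total loss fell from 3.519 (epoch 10) to 2.981 (epoch 200)
```

ARI/NMI near 1 mean the recovered domains almost coincide with the
simulated bands; the internal indices describe how cleanly the latent space
separates (SC > 0 and moderate DBI are typical for contiguous domains with
noisy boundaries). Other examples cover the augmentation algebra
(`augmentation_weights.py`), the agreement metrics on hand-checkable cases
(`evaluate_partitions.py`), morphology embedding without a pretrained
backbone (`morphology_features.py`), and the ablation harness
(`ablation_study.py`).

A thin CLI wraps the same pipeline:

```sh
vargg simulate -c sim.yaml -o fixture/
vargg run -c run.yaml -o out/
vargg ablate -c run.yaml --variants NG,NM,NGM,NV -o out/
vargg evaluate --labels out/domains.tsv --truth fixture/labels.tsv
```

## Input formats

* 10x Visium directory layout: `matrix.mtx(.gz)`, `barcodes.tsv(.gz)`,
  `features.tsv(.gz)`, `tissue_positions(_list).csv` (both dialects).
* Generic: dense TSV expression (spots × genes) + coordinate TSV
  (`spot_id, x, y`); labels as two-column TSV (`spot_id, domain`).
* Histology: PNG/TIFF image, or a precomputed spot × feature TSV.
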