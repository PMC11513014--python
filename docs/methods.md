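# Methods

## Model

One fused embedding per spot is learned from three signals: the
log-normalized expression matrix `Xg` (n spots × g genes), an image
feature matrix `Xm` (n × m, one embedding vector per spot supplied by
the user, typically from a CNN applied to the histology patch under each
spot), and the spatial kNN graph. The forward pass is

1. modality-specific affine maps `g → d1` and `m → d1`, followed by a
   single shared projection layer with a rectifier, giving `Hg`, `Hm`;
2. the feature mask: a subset `S` of spots, `|S| = round(p·n)`, drawn
   uniformly without replacement, has its gene row replaced by its image
   row. This is the modality-bias counter-measure: by randomly forcing
   image rows through the gene pathway, neither modality can dominate
   the shared encoder;
3. one two-layer graph convolution stack `d1 → d2 → d2` (first layer
   rectified, second linear, Kipf renormalized operator
   `D̂^{-1/2}(A+I)D̂^{-1/2}`) encodes *both* the masked gene view and the
   image view with the **same parameters**;
4. a gene-branch graph convolution `d2 → d3` and an image-branch affine
   map `d2 → d4` give `Zg`, `Zm`; an affine map on `concat(Zg, Zm)`
   gives `Zfusion` (n × d3).

Three objectives are summed, `L = α·L_mask + L_fusion + L_con` with
`α = 10`:

* `L_fusion = Σ_i ‖Xg_i − Linear(Zfusion)_i‖²` over all spots;
* `L_mask`  = the same squared error, from `Zg` through the **same**
  decoder, summed only over the masked spots — it anchors the gene
  branch so masking cannot erase expression information;
* `L_con`: a bilinear discriminator `σ(zᵀWγ)` scores each spot's
  embedding against its local context `γ_i = σ(mean of neighbor
  embeddings)`; positives are the real embeddings, negatives come from a
  full forward pass (mask disabled) on row-shuffled gene features fused
  with the unchanged image branch. The loss is the mean binary
  cross-entropy over the 2n scores. Discriminator outputs are clamped to
  `[1e-7, 1 − 1e-7]` so the logs stay finite.

Reconstruction losses use the summed (not mean) squared error; `α = 10`
is calibrated against this convention, and a mean-reduction flag exists
for users who rescale.

### Training and reproducibility

Full-graph gradient descent with Adam (lr 1e-3, β = 0.9/0.999), default
600 epochs (300 suffice on the synthetic benchmark). Gradients are
produced by `autograd` over a pure-numpy forward pass with a custom
sparse-matmul primitive, and the optimizer is implemented in the
package, so runs are bitwise reproducible for a fixed seed on a given
platform. Parameters are Glorot-uniform initialized from the run seed.
The masked subset is drawn once per run — stable reconstruction targets
for `L_mask` — with a `resample_mask` flag to redraw it each epoch; the
corruption permutation is redrawn every epoch. Training aborts with the
epoch index and component losses if any loss goes non-finite.

Two deliberate design choices where the architecture was open:

* the fusion "MLP" is a single affine layer on the concatenation; this
  keeps the fusion injectable/inspectable (an identity-slice weight
  matrix reproduces `Zg` exactly) and was sufficient for the benchmark;
* the final embedding handed to clustering comes from an inference-mode
  forward pass with the mask disabled, so every spot contributes its
  real gene features; the mask is a training-time regularizer only.

### Ablation switches

`ModelConfig` exposes `use_mask` (skip step 2), `share_weights` (give
the image pass its own encoder copy) and `use_contrastive` (drop
`L_con`). They exist to let users verify, on their own data, that each
component is non-harmful; on the synthetic benchmark the full model is
never inferior to any ablation.

## Graph

Directed kNN (Euclidean, k default 6 — the Visium hex neighbor count)
symmetrized by union so no spot is orphaned; ties in distance break by
lower spot index, making construction deterministic; duplicate
coordinates are legal. Self-loops exist only inside the propagation
operator; neighbor lists (used by the local context and by nothing
else) exclude self. Note the renormalized operator's row sums are not
bounded by 1 on irregular graphs — they reach `sqrt(d_max/d_min)` — and
equal 1 exactly on regular subgraphs; tests assert this corrected bound.

## Preprocessing

Per-spot library-size normalization to the median library, then
log(1+x). Gene variability is ranked by the variance of the
log-normalized values with ties broken by gene index, and the top 3000
genes are retained (all, if fewer). The normalized *pre-log* matrix is
kept alongside, because the SVG fold change is a ratio of means and is
only scale-meaningful on the linear scale. All-zero spots are an error
(they cannot be normalized), reported by spot ID. The normalization
recipe (median-library target, natural log) is a package choice;
both flags are configurable.

## Domain clustering

Default: Gaussian mixture with a shared ("tied") full covariance across
components, the common model for latent embeddings of layered tissue;
k-means and Leiden (resolution bisected toward the requested K) are
alternates. K is user-supplied — on annotated benchmarks it is the
number of annotated regions; no automatic model selection is attempted.
An optional majority-vote smoothing over graph neighbors is provided but
off by default. Agreement metrics are ARI and NMI.

## SVG detection

Per target domain `D`:

* **Radius calibration.** Bisection finds a radius at which target-domain
  spots average ~10 (±1, or closest achievable — the count is a step
  function) non-target spots within the closed ball. Calibrating per
  domain rather than globally keeps the "about 10 neighbors" behavior
  under uneven spot density; the procedure is deterministic and
  scale-equivariant.
* **Fine screen.** A non-target domain is *neighboring* iff strictly
  more than 50% of its spots fall in the union of those balls; the fold
  change `mean_D / (mean_DNF + 1e-9)` is computed over all spots of the
  neighboring domains, and genes pass at fold change strictly above 1.5.
  If no domain clears the 50% rule (common for wide layered domains,
  where only a sliver of the adjacent layer is within radius), the
  screen falls back to comparing against the raw neighbor set and warns.
* **Coarse screen.** One-sided Wilcoxon rank-sum (target > rest of
  tissue; Welch t as an option), BH-adjusted across genes, pass at
  adjusted p strictly below 0.05. Genes constant across all spots get
  adjusted p = 1.
* **Constraint screen.** The comparison pool is a `portion` (default
  all) of the non-neighboring domains ranked by size; a gene passes iff
  the target mean is *strictly* greater — equality fails. With no
  non-neighboring domains the screen passes everything, with a warning.
* **Final set** = intersection of the three; the report keeps all
  per-screen statistics in one long-format table.

All three thresholds are strict inequalities. Moran's I uses the same
spatial graph with row-normalized weights,
`I = (n/W)·Σ w_ij z_i z_j / Σ z_i²`; a constant gene returns 0 with a
warning (the statistic is undefined).

## Synthetic data

The generator emulates a Visium-like slide: spots on a square or hex
lattice; domains as contiguous layered bands (the cortical-layer
geometry; a Voronoi mosaic is the alternative); negative-binomial counts
(NB2, dispersion 0.5 — typical overdispersion for spot-level counts)
with per-gene base means uniform on [0.5, 3]; 10 marker genes per domain
whose mean is multiplied by 4 inside their domain; image features equal
to a per-domain standard-normal centroid vector (16 dims) plus Gaussian
noise of sd 0.5. The defaults (25×40 grid = 1000 spots, 4 domains, 200
genes) are the benchmark conditions used by the tests and the acceptance
script; `marker_effect=1` yields a null slide with no spatial signal,
used to check screen calibration.

What the simulation does **not** emulate: dropout/zero inflation beyond
NB sampling, spatial gradients within a domain, curved or nested domain
geometry, batch effects, segmentation errors in real histology features,
or any dependence between image noise and expression noise. Passing
tests therefore demonstrate correctness of the algorithms and sane
behavior under idealized spatial structure, not performance on real
tissue; on real data the image features in particular will be far less
cleanly domain-separated.

## Problem sizes and numerical notes

Tests and the acceptance script use the 1000-spot benchmark at 300
epochs (about 15–20 s per training run) and smaller slides for unit
checks; these sizes give stable statistics while keeping the suite
quick. Degenerate inputs are handled explicitly: zero-variance
embeddings abort clustering with advice to inspect training; an empty
masked subset makes `L_mask` exactly zero; isolated graph spots (only
possible in hand-built graphs) fall back to their own embedding in the
local context. The finite-difference gradient of the total loss matches
autograd to better than 1e-4 relative error on small instances, and all
closed-form statistics (losses, fold change, local context, Moran's I)
match brute-force reimplementations to 1e-10.

## Known limitations

* Full-graph training only; no mini-batching or GPU path, so very large
  slides (>~50k spots) will be slow.
* K must be supplied; no model selection for the number of domains.
* The fine screen's 50% rule rarely triggers for wide layered domains
  (fallback engages); the rule matters more for mosaic-like tissue.
* Image feature extraction from histology is out of scope: the package
  accepts any per-spot embedding but ships no CNN.
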