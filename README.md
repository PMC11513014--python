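# spadom

Spatial domain identification and domain-guided spatially variable gene
(SVG) detection for spatial transcriptomics.

Spatial transcriptomics assays (10x Visium, Stereo-seq, ...) measure a
gene expression profile at each of thousands of spatially located spots,
often alongside a histology image. Two recurring analysis tasks are
(1) partitioning the tissue into **spatial domains** — contiguous
regions with a shared expression program, such as cortical layers — and
(2) finding each domain's **spatially variable genes**, the genes whose
expression marks that region. `spadom` addresses both with a two-stage
pipeline aimed at analysts who have an expression matrix, spot
coordinates and (optionally) per-spot image-feature embeddings from a
pretrained CNN.

## Method

**Stage 1 — multi-modal domain identification.** Gene features $X_g \in
\mathbb{R}^{n\times g}$ and image features $X_m \in \mathbb{R}^{n\times
m}$ are projected into a shared space ($H_g, H_m \in \mathbb{R}^{n\times
d_1}$). To counter *modality bias* — the tendency of fused models to
lean on the dominant modality — a random subset $S\subset\{1..n\}$ of
spots (fraction $p$, default 0.1) has its gene row replaced by its image
row:

$$H_g' [i] = \begin{cases} H_m[i] & i \in S \\ H_g[i] & i \notin S\end{cases}$$

Both views are encoded by **one shared two-layer graph convolutional
encoder** on the spot kNN graph (operator
$\hat D^{-1/2}(A+I)\hat D^{-1/2}$, $k=6$), branch layers produce $Z_g$
and $Z_m$, and an affine fusion of $[Z_g, Z_m]$ gives the spot embedding
$Z_{\text{fusion}}$. Training minimizes

$$L = \alpha \sum_{i\in S}\lVert X_g[i] - \hat X^{(g)}[i]\rVert^2 \;+\;
\lVert X_g - \hat X^{(f)}\rVert_F^2 \;+\; L_{\text{con}}, \qquad \alpha = 10,$$

where both reconstructions $\hat X^{(g)} = \text{Linear}(Z_g)$ and
$\hat X^{(f)} = \text{Linear}(Z_{\text{fusion}})$ share one decoder, and
$L_{\text{con}}$ is a binary cross-entropy contrastive term: a bilinear
discriminator must score each spot's embedding against its *local
context* (sigmoid of the mean neighbor embedding) higher than the
embedding obtained from row-shuffled gene features. The fused embedding
is clustered into $K$ domains with a shared-covariance Gaussian mixture
(k-means and Leiden are alternates).

**Stage 2 — multi-granularity SVG detection.** For each domain $D$,
three screens are intersected:

* *fine-grained*: fold change $\tilde x_D / \tilde x_{D_{NF}} > 1.5$
  against the neighboring domains $D_{NF}$ (domains with >50% of their
  spots within a radius calibrated to give each spot of the target
  domain about 10 outside neighbors);
* *coarse-grained*: one-sided Wilcoxon rank-sum of $D$ versus all other
  spots, Benjamini–Hochberg adjusted, $p_{\text{adj}} < 0.05$;
* *constraint*: mean in $D$ strictly above the mean over the
  non-neighboring (distant) domains.

Moran's I on the spot graph quantifies the spatial coherence of the
detected genes. A synthetic-data module generates lattice slides with
planted domains, markers and surrogate image features so the whole
pipeline is testable end to end.

## Worked example

```bash
python examples/02_identify_domains.py
```

```
loss: 554336 (epoch 0) -> 148480 (epoch 299)
ARI = 1.000, NMI = 1.000
```

The model trains on a simulated 1000-spot slide with four layered
domains (loss falls ~4x over 300 epochs) and the Gaussian-mixture
clustering of the fused embedding recovers the planted layers exactly
(adjusted Rand index 1.0). Continuing with SVG detection
(`examples/03_detect_svgs.py`):

```
domain 0: fine 10, coarse 10, constraint 99 -> final 10
...
planted-marker recovery: recall 1.00, precision 1.00
median Moran's I of the 40 final SVGs: 0.29
```

Each domain's final SVG set is exactly its 10 planted markers, and their
median Moran's I (0.29) sits far above the spatial-null expectation of
about $-1/(n-1) \approx -0.001$.

The same pipeline runs from the shell:

```bash
spadom run --config config.yaml --seed 0        # full pipeline
spadom simulate --seed 0 --out slide/           # write a synthetic slide
spadom svg --expr expr.csv --coords coords.csv --domains domains.csv
```

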