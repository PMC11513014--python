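"""Identify spatial domains with the multi-modal model.

Pipeline: preprocess (library-size normalize, log1p, highly variable
genes) -> spatial kNN graph -> train the masked shared-encoder graph
model -> cluster the fused embedding with a shared-covariance Gaussian
mixture -> score against the planted labels.
"""

from spadom import (
    ModelConfig, SyntheticSpec, build_knn_graph, cluster_embedding,
    generate, preprocess, score_agreement, train,
)

ds_raw, _ = generate(SyntheticSpec(seed=0))
ds = preprocess(ds_raw)                      # keeps all 200 genes (< 3000)
graph = build_knn_graph(ds.coords, k=6)      # hex-like neighborhood size

cfg = ModelConfig(epochs=300, seed=0)        # alpha=10, mask fraction 0.1
state = train(ds, graph, cfg)
print(f"loss: {state.loss_trace[0, 3]:.0f} (epoch 0) -> "
      f"{state.loss_trace[-1, 3]:.0f} (epoch {cfg.epochs - 1})")

assignment = cluster_embedding(state.Zfusion, K=4, method="gmm", seed=0)
metrics = score_agreement(assignment.labels, ds_raw.labels)
print(f"ARI = {metrics['ari']:.3f}, NMI = {metrics['nmi']:.3f}")
# ARI 1.0 means the four layered domains are recovered exactly; the
# loss drop shows the reconstruction + contrastive objective training.
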