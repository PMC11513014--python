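"""Multi-modality representation learning for spatial domain identification.

The model learns one fused embedding per spot from three signals: gene
expression, image-derived features and the spatial neighbor graph. Its
pieces, in forward order:

1. *Modality projection.* Gene and image features pass through separate
   affine maps into a common dimension ``d1``, then through one shared
   projection layer with a rectifier, giving ``Hg`` and ``Hm``.
2. *Feature mask.* A fixed random subset of spots (fraction ``p``) has its
   gene row replaced by the corresponding image row. Substituting rows of
   the dominant modality with the weaker one counteracts modality bias.
3. *Shared graph encoder.* A two-layer graph convolution stack with a
   single parameter set encodes both the masked gene view and the image
   view, forcing a common latent geometry.
4. *Branches and fusion.* A gene-branch graph convolution and an image
   branch affine map produce ``Zg`` and ``Zm``; their concatenation is
   fused by an affine map into ``Zfusion``.
5. *Objectives.* Two reconstruction losses (full-matrix from ``Zfusion``,
   masked-rows-only from ``Zg``, both through one shared decoder) plus a
   contrastive loss that scores each spot's embedding against its local
   context via a bilinear discriminator, with row-shuffled gene features
   providing the negatives. Total loss: ``alpha * L_mask + L_fusion +
   L_contrastive``.

Everything is plain numpy; gradients come from ``autograd`` and the
optimizer is Adam implemented below, so training is bitwise reproducible
given a seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad
from autograd.extend import defvjp, primitive

from .graph import SpotGraph
from .datasets import SpatialDataset

__all__ = [
    "ModelConfig",
    "MaskPlan",
    "TrainState",
    "draw_mask_plan",
    "apply_feature_mask",
    "init_params",
    "shared_encode",
    "fuse",
    "loss_fusion",
    "loss_gene_mask",
    "loss_contrastive",
    "total_loss",
    "forward",
    "train",
]


# sparse @ dense as an autograd primitive; the sparse operator is constant
@primitive
def _spmm(S, X):
    return S @ X


defvjp(_spmm, None, lambda ans, S, X: lambda g: S.T @ g)


def _relu(x):
    return anp.maximum(x, 0.0)


def _sigmoid(x):
    return 1.0 / (1.0 + anp.exp(-x))


@dataclass
class ModelConfig:
    """Hyperparameters of the multi-modal model.

    ``d1`` is the shared projection width, ``d2`` the shared-encoder
    output, ``d3`` the gene-branch/fusion width (the embedding that is
    clustered), ``d4`` the image-branch width. ``mask_fraction`` is the
    fraction of spots whose gene row is replaced by its image row.
    ``alpha`` weights the masked-reconstruction loss in the total
    objective. The ablation switches turn off the feature mask, encoder
    weight sharing, or the contrastive term, leaving the rest intact.
    """

    d1: int = 128
    d2: int = 64
    d3: int = 64
    d4: int = 64
    mask_fraction: float = 0.1
    alpha: float = 10.0
    epochs: int = 600
    learning_rate: float = 1e-3
    seed: int = 0
    resample_mask: bool = False  # redraw the masked subset every epoch
    mean_reduction: bool = False  # mean instead of sum in reconstruction losses
    use_mask: bool = True
    share_weights: bool = True
    use_contrastive: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.mask_fraction <= 1.0:
            raise ValueError("mask_fraction must be in [0, 1]")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if min(self.d1, self.d2, self.d3, self.d4) < 1:
            raise ValueError("all embedding dims must be positive")


@dataclass
class MaskPlan:
    """The spot subset whose gene rows are replaced by image rows."""

    masked_indices: np.ndarray
    n_spots: int

    def __post_init__(self) -> None:
        self.masked_indices = np.asarray(self.masked_indices, dtype=np.int64)
        if len(np.unique(self.masked_indices)) != len(self.masked_indices):
            raise ValueError("masked indices must be unique")
        if self.masked_indices.size and (
            self.masked_indices.min() < 0 or self.masked_indices.max() >= self.n_spots
        ):
            raise ValueError("masked index out of range")

    @property
    def fraction_realized(self) -> float:
        return len(self.masked_indices) / self.n_spots


def draw_mask_plan(n_spots: int, fraction: float, rng: np.random.Generator) -> MaskPlan:
    """Sample round(fraction * n) distinct spot indices."""
    size = int(round(fraction * n_spots))
    idx = rng.choice(n_spots, size=size, replace=False) if size else np.empty(0, dtype=np.int64)
    return MaskPlan(masked_indices=np.sort(idx), n_spots=n_spots)


def apply_feature_mask(Hg, Hm, plan: MaskPlan):
    """Row-wise substitution: masked spots take the image row, others the gene row."""
    if Hg.shape != Hm.shape:
        raise ValueError("Hg and Hm must have the same shape")
    if plan.n_spots != Hg.shape[0]:
        raise ValueError("mask plan was drawn for a different number of spots")
    mask = np.zeros((plan.n_spots, 1), dtype=bool)
    mask[plan.masked_indices] = True
    return anp.where(mask, Hm, Hg)


def init_params(g: int, m: int, cfg: ModelConfig, rng: np.random.Generator) -> dict:
    """Uniform fan-based (Glorot) initialization of every learnable map."""

    def glorot(fan_in, fan_out):
        a = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-a, a, size=(fan_in, fan_out))

    d1, d2, d3, d4 = cfg.d1, cfg.d2, cfg.d3, cfg.d4
    params = {
        "gene_linear_W": glorot(g, d1), "gene_linear_b": np.zeros(d1),
        "image_linear_W": glorot(m, d1), "image_linear_b": np.zeros(d1),
        "proj_W": glorot(d1, d1), "proj_b": np.zeros(d1),
        "shared_gcn_W1": glorot(d1, d2), "shared_gcn_b1": np.zeros(d2),
        "shared_gcn_W2": glorot(d2, d2), "shared_gcn_b2": np.zeros(d2),
        "gene_branch_W": glorot(d2, d3), "gene_branch_b": np.zeros(d3),
        "image_branch_W": glorot(d2, d4), "image_branch_b": np.zeros(d4),
        "fusion_W": glorot(d3 + d4, d3), "fusion_b": np.zeros(d3),
        "decoder_W": glorot(d3, g), "decoder_b": np.zeros(g),
        "disc_W": glorot(d3, d3),
    }
    if not cfg.share_weights:
        # separate encoder copy for the image pass (ablation of weight sharing)
        params.update({
            "shared_gcn_W1_img": glorot(d1, d2), "shared_gcn_b1_img": np.zeros(d2),
            "shared_gcn_W2_img": glorot(d2, d2), "shared_gcn_b2_img": np.zeros(d2),
        })
    return params


def _project(params, X, which):
    H = X @ params[f"{which}_linear_W"] + params[f"{which}_linear_b"]
    return _relu(H @ params["proj_W"] + params["proj_b"])


def shared_encode(params, H, graph: SpotGraph, suffix: str = ""):
    """Two-layer graph convolution with the shared parameter set.

    First layer rectified, second linear. The ``suffix`` selects the
    separate image-encoder copy when weight sharing is ablated.
    """
    S = graph.norm_operator
    if S.shape[0] != H.shape[0]:
        raise ValueError("graph size does not match feature rows")
    Z = _relu(_spmm(S, H) @ params["shared_gcn_W1" + suffix] + params["shared_gcn_b1" + suffix])
    return _spmm(S, Z) @ params["shared_gcn_W2" + suffix] + params["shared_gcn_b2" + suffix]


def _gene_branch(params, Z1, graph: SpotGraph):
    return _spmm(graph.norm_operator, Z1) @ params["gene_branch_W"] + params["gene_branch_b"]


def _image_branch(params, Z1):
    return Z1 @ params["image_branch_W"] + params["image_branch_b"]


def fuse(params, Zg, Zm):
    """Fusion of branch embeddings: affine map on concat(gene, image)."""
    if Zg.shape[0] != Zm.shape[0]:
        raise ValueError("row counts of Zg and Zm differ")
    return anp.concatenate([Zg, Zm], axis=1) @ params["fusion_W"] + params["fusion_b"]


def _decode(params, Z):
    return Z @ params["decoder_W"] + params["decoder_b"]


def discriminate(params, Z, G):
    """Bilinear discriminator sigma(z_i^T W g_i) per spot."""
    return _sigmoid(anp.sum((Z @ params["disc_W"]) * G, axis=1))


def loss_fusion(Xg, recon, mean_reduction: bool = False):
    """Squared reconstruction error of the full expression matrix."""
    sq = anp.sum((Xg - recon) ** 2)
    return sq / Xg.size if mean_reduction else sq


def loss_gene_mask(Xg, recon_gene, plan: MaskPlan, mean_reduction: bool = False):
    """Squared reconstruction error restricted to the masked spots."""
    idx = plan.masked_indices
    if idx.size == 0:
        return 0.0 * anp.sum(recon_gene)  # keep graph connected for autograd
    sq = anp.sum((Xg[idx] - recon_gene[idx]) ** 2)
    return sq / (idx.size * Xg.shape[1]) if mean_reduction else sq


_EPS = 1e-7


def loss_contrastive(pos_scores, neg_scores):
    """Binary cross-entropy over positive (real, context) and negative
    (corrupted, context) pairs, averaged over 2n scores."""
    p = anp.clip(pos_scores, _EPS, 1.0 - _EPS)
    q = anp.clip(neg_scores, _EPS, 1.0 - _EPS)
    n = p.shape[0]
    return -(anp.sum(anp.log(p)) + anp.sum(anp.log(1.0 - q))) / (2.0 * n)


def total_loss(l_mask, l_fusion, l_sup, alpha: float):
    return alpha * l_mask + l_fusion + l_sup


def forward(
    params: dict,
    Xg: np.ndarray,
    Xm: np.ndarray,
    graph: SpotGraph,
    plan: MaskPlan,
    cfg: ModelConfig,
    permutation: np.ndarray | None = None,
    context_operator=None,
) -> dict:
    """One full forward pass; returns embeddings, scores and losses.

    ``permutation`` drives the corrupted (negative) pass: the shuffled
    gene features take the identical path — projection, shared encoder,
    gene branch, fusion with the *unchanged* image branch — with the
    feature mask disabled. ``context_operator`` is the row-normalized
    adjacency (precomputed by the caller; falls back to the graph's own).
    """
    Hg = _project(params, Xg, "gene")
    Hm = _project(params, Xm, "image")
    Hg_in = apply_feature_mask(Hg, Hm, plan) if cfg.use_mask else Hg

    img_suffix = "" if cfg.share_weights else "_img"
    Z1g = shared_encode(params, Hg_in, graph)
    Z1m = shared_encode(params, Hm, graph, suffix=img_suffix)
    Zg = _gene_branch(params, Z1g, graph)
    Zm = _image_branch(params, Z1m)
    Zfusion = fuse(params, Zg, Zm)

    l_fusion = loss_fusion(Xg, _decode(params, Zfusion), cfg.mean_reduction)
    l_mask = loss_gene_mask(Xg, _decode(params, Zg), plan, cfg.mean_reduction)

    out = {"Zg": Zg, "Zm": Zm, "Zfusion": Zfusion, "l_fusion": l_fusion, "l_mask": l_mask}

    if cfg.use_contrastive and permutation is not None:
        M = context_operator if context_operator is not None else graph.row_normalized_adjacency()
        G = _sigmoid(_spmm(M, Zfusion))
        Hg_c = _project(params, Xg[permutation], "gene")
        Z1g_c = shared_encode(params, Hg_c, graph)
        Zg_c = _gene_branch(params, Z1g_c, graph)
        Zf_c = fuse(params, Zg_c, Zm)
        pos = discriminate(params, Zfusion, G)
        neg = discriminate(params, Zf_c, G)
        out.update(pos_scores=pos, neg_scores=neg, l_sup=loss_contrastive(pos, neg))
    else:
        out["l_sup"] = 0.0
    out["l_total"] = total_loss(out["l_mask"], out["l_fusion"], out["l_sup"], cfg.alpha)
    return out


@dataclass
class TrainState:
    """Result of a training run: final parameters, embeddings, loss trace."""

    params: dict
    config: ModelConfig
    mask_plan: MaskPlan
    loss_trace: np.ndarray = field(repr=False)  # (epochs, 4): l_mask, l_fusion, l_sup, l_total
    Zfusion: np.ndarray = field(repr=False)
    Zg: np.ndarray = field(repr=False)
    Zm: np.ndarray = field(repr=False)

    def trace_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.loss_trace, columns=["l_mask", "l_fusion", "l_sup", "l_total"]
        ).rename_axis("epoch")

    def save(self, prefix: str) -> None:
        """Write weights (`<prefix>.npz`), config sidecar and loss trace CSV."""
        os.makedirs(os.path.dirname(prefix) or ".", exist_ok=True)
        np.savez(prefix + ".npz", **self.params)
        cfg = asdict(self.config)
        with open(prefix + ".json", "w") as fh:
            json.dump(cfg, fh, indent=2)
        self.trace_frame().to_csv(prefix + "_trace.csv")


class _Adam:
    def __init__(self, params: dict, lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: dict, grads: dict) -> dict:
        self.t += 1
        out = {}
        bc1 = 1.0 - self.beta1 ** self.t
        bc2 = 1.0 - self.beta2 ** self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            out[k] = p - self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
        return out


def train(ds: SpatialDataset, graph: SpotGraph, cfg: ModelConfig) -> TrainState:
    """Full-graph training of the multi-modal model.

    The masked subset is drawn once at the start (stable reconstruction
    targets; set ``cfg.resample_mask`` to redraw each epoch) and a fresh
    corruption permutation is drawn every epoch. Reproducible bitwise
    given ``cfg.seed``. The final embeddings come from an inference-mode
    forward pass with the mask disabled, so every spot contributes its
    real gene features to the embedding that is clustered.
    """
    if ds.image_feats is None:
        raise ValueError(
            "training requires image features; supply them or generate "
            "surrogates (see synthetic data module)"
        )
    Xg = np.asarray(ds.expr, dtype=float)
    Xm = np.asarray(ds.image_feats, dtype=float)
    n = Xg.shape[0]
    if graph.n_spots != n:
        raise ValueError("graph size does not match dataset")

    rng = np.random.default_rng(cfg.seed)
    params = init_params(Xg.shape[1], Xm.shape[1], cfg, rng)
    plan = draw_mask_plan(n, cfg.mask_fraction if cfg.use_mask else 0.0, rng)
    M = graph.row_normalized_adjacency()
    opt = _Adam(params, cfg.learning_rate)

    trace = np.zeros((cfg.epochs, 4))
    aux: dict = {}

    def _unbox(x):
        while hasattr(x, "_value"):
            x = x._value
        return float(x)

    def objective(p, perm, plan):
        out = forward(p, Xg, Xm, graph, plan, cfg, permutation=perm, context_operator=M)
        aux["comp"] = out
        return out["l_total"]

    grad_fn = value_and_grad(objective)

    for epoch in range(cfg.epochs):
        if cfg.resample_mask and cfg.use_mask:
            plan = draw_mask_plan(n, cfg.mask_fraction, rng)
        perm = rng.permutation(n) if cfg.use_contrastive else None
        loss, grads = grad_fn(params, perm, plan)
        comp = aux["comp"]
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite loss at epoch {epoch}: "
                f"l_mask={_unbox(comp['l_mask'])}, "
                f"l_fusion={_unbox(comp['l_fusion'])}, "
                f"l_sup={_unbox(comp['l_sup'])}"
            )
        trace[epoch] = [
            _unbox(comp["l_mask"]), _unbox(comp["l_fusion"]),
            _unbox(comp["l_sup"]), _unbox(comp["l_total"]),
        ]
        params = opt.step(params, grads)

    # inference pass: mask off, no corruption
    infer_cfg = ModelConfig(**{**asdict(cfg), "use_mask": False})
    final = forward(params, Xg, Xm, graph, plan, infer_cfg, permutation=None, context_operator=M)
    if not np.all(np.isfinite(final["Zfusion"])):
        raise RuntimeError("non-finite entries in final embedding")
    return TrainState(
        params=params,
        config=cfg,
        mask_plan=plan,
        loss_trace=trace,
        Zfusion=np.asarray(final["Zfusion"]),
        Zg=np.asarray(final["Zg"]),
        Zm=np.asarray(final["Zm"]),
    )
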