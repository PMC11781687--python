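"""Graph encoder, projection head, discriminators and the three losses.

The encoder is a GCN: H = act(A_hat X W) with the symmetric-normalized
self-loop adjacency A_hat = D^{-1/2}(A + I)D^{-1/2}; K=1 propagation keeps
node embeddings distinguishable on these small dense-ish graphs (a GAT
layer is available as an alternative, without the same guarantees).

Three objectives are combined:

* supervised — binary cross-entropy of sigmoid inner-product pair scores
  against observed sensitive/resistant labels;
* node-level contrastive — InfoNCE between the feature-masked and the
  edge-pruned view of one graph: the same node in the other view is the
  positive, all other nodes in either view are negatives, with cosine
  similarity at temperature tau after a two-layer MLP projection;
* graph-level contrastive — a bilinear discriminator scores nodes against a
  sigmoid mean-pool graph summary; nodes of the sensitivity graph are
  positives for its own summary and nodes of the resistance (complement)
  graph are negatives, symmetrized across the two summaries.

Each printed objective is an agreement score maximized by the model; the
implemented losses are their negations so that the weighted total is
minimized.  Total = alpha * sup + beta * node + gamma * graph with
alpha + beta + gamma = 1 (defaults 0.4 / 0.4 / 0.2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from ._tensor import Tensor, as_tensor, take_rows

__all__ = [
    "EncoderConfig", "LossWeights",
    "normalized_adjacency", "propagate_layer", "gat_layer", "encode",
    "cosine_discriminator", "node_contrastive_loss", "readout_summary",
    "bilinear_discriminator", "graph_contrastive_loss", "pair_scores",
    "supervised_loss", "total_loss",
]

_CLIP = 1e-7


@dataclass
class EncoderConfig:
    """Encoder and projection-head hyperparameters.

    ``dims`` are the per-layer output sizes of the K propagation layers
    (the input size is the shared fused-feature dimension); ``tau`` is the
    InfoNCE temperature.  Defaults mirror the reference setting: one GCN
    layer mapping the 224-dim shared space to 24-dim embeddings.
    """
    encoder_type: Literal["gcn", "gat"] = "gcn"
    dims: tuple[int, ...] = (24,)
    tau: float = 0.5
    projection_dims: tuple[int, int] = (24, 24)
    activation_slope: float = 0.2

    def __post_init__(self):
        if len(self.dims) < 1:
            raise ValueError("need at least one encoder layer")
        if self.tau <= 0:
            raise ValueError("temperature tau must be > 0")

    @property
    def K(self) -> int:
        return len(self.dims)


@dataclass
class LossWeights:
    """Convex combination weights (alpha, beta, gamma) of the three losses."""
    alpha: float = 0.4
    beta: float = 0.4
    gamma: float = 0.2

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("loss weights must be nonnegative")
        if abs(self.alpha + self.beta + self.gamma - 1.0) > 1e-8:
            raise ValueError("loss weights must sum to 1")


def _plain_scalar(out: Tensor, *inputs):
    if any(isinstance(x, Tensor) for x in inputs):
        return out
    return float(out.data)


def normalized_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric-normalized adjacency with self-loops, D^{-1/2}(A+I)D^{-1/2}."""
    A = np.asarray(A, dtype=float)
    A_tilde = A + np.eye(A.shape[0])
    d = A_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return A_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]


def propagate_layer(X, A, W, slope: float = 0.2, *, A_is_normalized: bool = False):
    """One GCN layer: act(A_hat @ X @ W) with a leaky-rectifier activation."""
    Xt, Wt = as_tensor(X), as_tensor(W)
    if Xt.shape[1] != Wt.shape[0]:
        raise ValueError("feature/weight dimensions do not conform")
    A_hat = np.asarray(A, float) if A_is_normalized else normalized_adjacency(A)
    out = (as_tensor(A_hat) @ Xt @ Wt).leaky_relu(slope)
    if isinstance(X, Tensor) or isinstance(W, Tensor):
        return out
    return out.data


def gat_layer(X, A, W, a_src, a_dst, slope: float = 0.2):
    """Single-head graph attention layer over the self-loop neighborhood."""
    Xt, Wt = as_tensor(X), as_tensor(W)
    Z = Xt @ Wt
    e_src = Z @ as_tensor(np.asarray(a_src, float).reshape(-1, 1))
    e_dst = Z @ as_tensor(np.asarray(a_dst, float).reshape(-1, 1))
    logits = (e_src + e_dst.T).leaky_relu(slope)
    mask = (np.asarray(A, float) + np.eye(Xt.shape[0])) > 0
    weights = logits.exp() * mask.astype(float)
    att = weights / weights.sum(axis=1, keepdims=True)
    return (att @ Z).leaky_relu(slope)


def encode(X, A, weights: Sequence, config: EncoderConfig | None = None,
           *, A_is_normalized: bool = False):
    """Stack K propagation layers (weights is one matrix per layer)."""
    cfg = config or EncoderConfig()
    H = X
    for layer in weights:
        if cfg.encoder_type == "gat":
            W, a_src, a_dst = layer
            H = gat_layer(H, A, W, a_src, a_dst, cfg.activation_slope)
        else:
            H = propagate_layer(H, A, layer, cfg.activation_slope,
                                A_is_normalized=A_is_normalized)
    return H


def _row_normalize(Z: Tensor) -> Tensor:
    norms = ((Z * Z).sum(axis=1, keepdims=True) + 1e-12).sqrt()
    return Z / norms


def cosine_discriminator(z_u, z_v) -> float:
    """Cosine similarity of two (projected) embedding vectors."""
    u = np.asarray(z_u.data if isinstance(z_u, Tensor) else z_u, float).ravel()
    v = np.asarray(z_v.data if isinstance(z_v, Tensor) else z_v, float).ravel()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(u @ v / (nu * nv))


def node_contrastive_loss(Z_u, Z_v, tau: float = 0.5):
    """InfoNCE over two views with intra- and inter-view negatives.

    For anchor u_i the positive is v_i; negatives are u_k and v_k for all
    k != i.  Similarities are cosines over tau.  Both anchor directions are
    averaged and negated, so the returned loss is >= 0 and is minimized when
    matched nodes agree across views.
    """
    Zu, Zv = as_tensor(Z_u), as_tensor(Z_v)
    N = Zu.shape[0]
    if Zv.shape[0] != N:
        raise ValueError("views must contain the same nodes in the same order")
    if N < 2:
        raise ValueError("need at least 2 nodes for negative samples")
    Un, Vn = _row_normalize(Zu), _row_normalize(Zv)
    inv_tau = 1.0 / tau
    E_uv = ((Un @ Vn.T) * inv_tau).exp()
    E_uu = ((Un @ Un.T) * inv_tau).exp()
    E_vv = ((Vn @ Vn.T) * inv_tau).exp()
    eye = np.eye(N)
    off = 1.0 - eye

    def _direction(E_pos, E_intra):
        pos = (E_pos * eye).sum(axis=1)
        denom = pos + (E_intra * off).sum(axis=1) + (E_pos * off).sum(axis=1)
        return (pos / denom).log().mean()

    h_u = _direction(E_uv, E_uu)
    h_v = _direction(E_uv.T, E_vv)
    loss = (h_u + h_v) * -0.5
    return _plain_scalar(loss, Z_u, Z_v)


def readout_summary(H):
    """Graph-level summary: sigmoid of the node-wise mean embedding."""
    Ht = as_tensor(H)
    out = Ht.mean(axis=0).sigmoid()
    if isinstance(H, Tensor):
        return out
    return out.data


def bilinear_discriminator(h, V, W_V):
    """phi(h, V) = sigmoid(h^T W_V V): node-vs-summary agreement score.

    ``h`` may be a single embedding (d,) or a stack (N, d); ``V`` is the
    graph summary (d,).  Returns scores in (0, 1) of matching shape.
    """
    ht, Vt, Wt = as_tensor(h), as_tensor(V), as_tensor(W_V)
    single = ht.ndim == 1
    if single:
        ht = ht.reshape(1, -1)
    scores = (ht @ Wt @ Vt.reshape(-1, 1)).sigmoid().reshape(-1)
    if single:
        scores = scores.sum()  # scalar
    if any(isinstance(x, Tensor) for x in (h, V, W_V)):
        return scores
    return float(scores.data) if single else scores.data


def graph_contrastive_loss(H_pos, H_neg, V, U, W_V):
    """Deep-infomax style discrimination of nodes against graph summaries.

    f(pos, neg, V) = sum_i log phi(pos_i, V) + sum_i log(1 - phi(neg_i, V));
    the loss is -(1/2N) [f(H_pos, H_neg, V) + f(H_neg, H_pos, U)], i.e. each
    graph's own nodes should score high against its own summary and the
    opposing (complement-topology) nodes low.
    """
    Hp, Hn = as_tensor(H_pos), as_tensor(H_neg)
    Vt, Ut, Wt = as_tensor(V), as_tensor(U), as_tensor(W_V)
    N = Hp.shape[0]

    def _phi(H, summary):
        return (H @ Wt @ summary.reshape(-1, 1)).sigmoid().clip(_CLIP, 1.0 - _CLIP)

    f1 = _phi(Hp, Vt).log().sum() + (1.0 - _phi(Hn, Vt)).log().sum()
    f2 = _phi(Hn, Ut).log().sum() + (1.0 - _phi(Hp, Ut)).log().sum()
    loss = (f1 + f2) * (-1.0 / (2.0 * N))
    return _plain_scalar(loss, H_pos, H_neg, V, U, W_V)


def pair_scores(H, pairs, m: int, n: int):
    """Sigmoid inner-product scores for (cell, drug) index pairs.

    ``pairs`` holds (cell index, drug index) rows; cell nodes occupy rows
    [0, m) of H and drug nodes rows [m, m+n).
    """
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    if pairs.size and (pairs[:, 0].min() < 0 or pairs[:, 0].max() >= m):
        raise ValueError("cell index outside the cell partition")
    if pairs.size and (pairs[:, 1].min() < 0 or pairs[:, 1].max() >= n):
        raise ValueError("drug index outside the drug partition")
    Ht = as_tensor(H)
    h_c = take_rows(Ht, pairs[:, 0])
    h_d = take_rows(Ht, m + pairs[:, 1])
    out = (h_c * h_d).sum(axis=1).sigmoid()
    return out if isinstance(H, Tensor) else out.data


def supervised_loss(P_pred, P_lab):
    """Mean binary cross-entropy with probability clipping at 1e-7."""
    p = as_tensor(P_pred)
    y = np.asarray(P_lab.data if isinstance(P_lab, Tensor) else P_lab, float)
    if p.data.size == 0:
        raise ValueError("empty batch")
    pc = p.clip(_CLIP, 1.0 - _CLIP)
    loss = -(as_tensor(y) * pc.log() + as_tensor(1.0 - y) * (1.0 - pc).log()).mean()
    return _plain_scalar(loss, P_pred)


def total_loss(L_sup, L_nod, L_gra, weights: LossWeights):
    """Convex combination alpha*sup + beta*node + gamma*graph."""
    out = weights.alpha * as_tensor(L_sup) + weights.beta * as_tensor(L_nod) \
        + weights.gamma * as_tensor(L_gra)
    return _plain_scalar(out, L_sup, L_nod, L_gra)
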