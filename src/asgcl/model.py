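"""End-to-end trainable model: subspace fusion, graph encoder and heads.

All learnable parameters live here; the nonlinear subspace is trained
jointly with the encoder and heads in a single computational graph, so
the fused node features co-adapt with the contrastive and supervised
objectives.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor
from .contrastive import EncoderConfig, encode, pair_scores
from .subspace import FeatureBundle, linear_features, linear_transform

__all__ = ["ASGCLModel"]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=(fan_in, fan_out)),
                  requires_grad=True)


class ASGCLModel:
    """Parameters and forward pieces of the full pipeline.

    Parameters
    ----------
    n_cell_feat, n_drug_feat:
        Raw input dimensions (all omics layers concatenated; fingerprint bits).
    d_shared:
        Shared fused-feature dimension (the linear and nonlinear paths of
        both entities all map into this space).
    config:
        Encoder/projection/temperature settings.
    seed:
        Seed for parameter initialization.
    """

    def __init__(self, n_cell_feat: int, n_drug_feat: int, d_shared: int = 224,
                 config: EncoderConfig | None = None, seed: int = 0):
        self.config = config or EncoderConfig()
        self.d_shared = d_shared
        rng = np.random.default_rng(seed)
        # linear path
        self.W_c = _glorot(rng, n_cell_feat, d_shared)
        self.W_d = _glorot(rng, n_drug_feat, d_shared)
        self.omega1 = Tensor(1.0, requires_grad=True)
        self.omega2 = Tensor(1.0, requires_grad=True)
        # nonlinear path (one-hop propagation over similarity graphs)
        self.W_nl_c = _glorot(rng, n_cell_feat, d_shared)
        self.W_nl_d = _glorot(rng, n_drug_feat, d_shared)
        # graph encoder (K layers)
        self.enc_weights = []
        d_in = d_shared
        for d_out in self.config.dims:
            if self.config.encoder_type == "gat":
                self.enc_weights.append((
                    _glorot(rng, d_in, d_out),
                    Tensor(rng.uniform(-0.1, 0.1, d_out), requires_grad=True),
                    Tensor(rng.uniform(-0.1, 0.1, d_out), requires_grad=True)))
            else:
                self.enc_weights.append(_glorot(rng, d_in, d_out))
            d_in = d_out
        d_emb = d_in
        # two-layer MLP projection head for the node-level discriminator
        p1, p2 = self.config.projection_dims
        self.W_p1 = _glorot(rng, d_emb, p1)
        self.W_p2 = _glorot(rng, p1, p2)
        # bilinear scoring matrix for the graph-level discriminator
        self.W_V = _glorot(rng, d_emb, d_emb)

    # -- parameter plumbing ---------------------------------------------
    def parameters(self) -> list[Tensor]:
        params = [self.W_c, self.W_d, self.omega1, self.omega2,
                  self.W_nl_c, self.W_nl_d]
        for layer in self.enc_weights:
            params.extend(layer if isinstance(layer, tuple) else (layer,))
        params.extend([self.W_p1, self.W_p2, self.W_V])
        return params

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p.data = s.copy()

    # -- forward pieces --------------------------------------------------
    def fuse_features(self, C: np.ndarray, D: np.ndarray,
                      n_c: np.ndarray, n_d: np.ndarray,
                      AC_prop: np.ndarray, AD_prop: np.ndarray) -> FeatureBundle:
        """Fused features X = LF + NLF for both entities.

        AC_prop / AD_prop are the propagated raw features A_hat @ C and
        A_hat @ D over the similarity graphs (constant across epochs, so
        precomputed by the caller).
        """
        E_c, E_d = linear_transform(C, D, self.W_c, self.W_d)
        lf_c, lf_d = linear_features(E_c, E_d, n_c, n_d, self.omega1, self.omega2)
        slope = self.config.activation_slope
        nlf_c = (Tensor(AC_prop) @ self.W_nl_c).leaky_relu(slope)
        nlf_d = (Tensor(AD_prop) @ self.W_nl_d).leaky_relu(slope)
        return FeatureBundle(LF_cell=lf_c, LF_drug=lf_d,
                             NLF_cell=nlf_c, NLF_drug=nlf_d)

    def encode(self, X, A_hat, *, A_is_normalized: bool = True):
        """K-layer graph encoding with the model's weights.

        A_hat is expected pre-normalized (the training loop caches it).
        """
        return encode(X, A_hat, self.enc_weights, self.config,
                      A_is_normalized=A_is_normalized)

    def project(self, H):
        """Two-layer MLP projection for the node-level contrast."""
        slope = self.config.activation_slope
        return (H @ self.W_p1).leaky_relu(slope) @ self.W_p2

    def score_pairs(self, H, pairs, m: int, n: int):
        return pair_scores(H, pairs, m, n)
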