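"""Adaptive graph augmentation (GraphMorpher).

Two stochastic views are generated from a graph each training iteration:

* a feature-masked view — whole feature dimensions are zeroed, with
  dimensions that carry little centrality-weighted signal masked more often;
* an edge-pruned view — edges incident to low-centrality nodes are dropped
  more often, preserving the high-centrality backbone.

Importance is measured by eigenvector centrality F (leading eigenvector of
the adjacency).  Mask/prune probabilities scale with the deficit of a
dimension's (or edge's) weight below the maximum, capped by a truncation
probability so the graph is never destructively sparsified.  The complement
("resistance") graph is obtained by inverting the bipartite blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .subspace import HeteroGraph

__all__ = [
    "AugmentParams", "CentralityProfile", "AugmentedViews",
    "invert_adjacency", "eigenvector_centrality", "feature_mask_weights",
    "adaptive_probabilities", "sample_feature_mask", "edge_weights",
    "sample_edge_pruning", "centrality_profile", "morph",
]

_EPS = 1e-12


@dataclass
class AugmentParams:
    """Augmentation strengths and truncation caps, all in [0, 1].

    rho_n / rho_l scale the feature-mask and edge-prune probabilities;
    t_n / t_l cap them.  Defaults follow the parameter study optimum:
    rho_n=0.2, rho_l=0.3, caps 0.3 and 0.4.
    """
    rho_n: float = 0.2
    rho_l: float = 0.3
    t_n: float = 0.3
    t_l: float = 0.4

    def __post_init__(self):
        for name in ("rho_n", "rho_l", "t_n", "t_l"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class CentralityProfile:
    """Centrality-derived weights for one graph."""
    F: np.ndarray        # per-node eigenvector centrality, ||F||_2 = 1
    M_N: np.ndarray      # per-feature-dimension mask weight
    M_L: np.ndarray      # per-edge prune weight (order of `edges`)
    edges: np.ndarray    # (n_edges, 2) undirected edge list, i < j


@dataclass
class AugmentedViews:
    """The two stochastic views of one graph."""
    G_N: HeteroGraph     # masked features, original adjacency
    G_L: HeteroGraph     # original features, pruned adjacency
    mask: np.ndarray     # per-dimension keep indicator m
    retained_edges: np.ndarray


def invert_adjacency(G: HeteroGraph) -> HeteroGraph:
    """Complement the bipartite blocks: sensitivity <-> resistance.

    Off-diagonal cell x drug entries are flipped (1 - A); within-partition
    entries and the diagonal stay zero, so bipartiteness is preserved and
    the operation is an involution.
    """
    m, n = G.m, G.n
    A = np.zeros_like(G.A)
    block = 1.0 - G.A[:m, m:]
    A[:m, m:] = block
    A[m:, :m] = block.T
    polarity = "resistance" if G.polarity == "sensitivity" else "sensitivity"
    return HeteroGraph(G.X, A, m, n, polarity=polarity)


def eigenvector_centrality(A: np.ndarray, tol: float = 1e-8,
                           max_iter: int = 10_000) -> np.ndarray:
    """Leading eigenvector of a symmetric nonnegative adjacency.

    Power iteration from a uniform start with an additive epsilon that keeps
    isolated nodes at a tiny positive value; the result has unit L2 norm.
    The iteration runs on A + I: a bipartite adjacency has eigenvalues in
    +/- pairs, so the unshifted iteration would oscillate, while the unit
    diagonal shift leaves eigenvectors unchanged and makes the Perron
    eigenvalue strictly dominant.
    """
    A = np.asarray(A, dtype=float)
    N = A.shape[0]
    x = np.full(N, 1.0 / np.sqrt(N))
    for _ in range(max_iter):
        y = A @ x + x + _EPS
        y /= np.linalg.norm(y)
        if np.abs(y - x).max() < tol:
            return y
        x = y
    y = A @ x + x
    residual = float(np.abs(y / max(np.linalg.norm(y), _EPS) - x).max())
    raise RuntimeError(f"power iteration did not converge; residual={residual:.2e}")


def feature_mask_weights(X: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Per-dimension importance: M_N[i] = sum_v |X[v, i]| * F[v].

    Dimensions that carry large magnitudes on central nodes score high and
    are masked least.
    """
    X = np.asarray(X, dtype=float)
    F = np.asarray(F, dtype=float)
    if X.shape[0] != F.shape[0]:
        raise ValueError("centrality length must equal the node count")
    return np.abs(X).T @ F


def adaptive_probabilities(M: np.ndarray, rho: float, T: float) -> np.ndarray:
    """P_i = min(rho * (M_max - M_i) / (M_max - mean(M)), T).

    The maximal-weight item gets probability 0; items below the mean exceed
    rho and are capped at T.  When all weights are equal the denominator
    vanishes and every probability is defined as 0 (no augmentation).
    """
    M = np.asarray(M, dtype=float)
    m_max, mu = M.max(), M.mean()
    if m_max == mu:
        return np.zeros_like(M)
    return np.minimum(rho * (m_max - M) / (m_max - mu), T)


def sample_feature_mask(X: np.ndarray, p_mask: np.ndarray,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Zero whole feature dimensions: m_i ~ Bernoulli(1 - p_mask[i]).

    Returns (keep indicator m, masked features X * m).
    """
    p_mask = np.asarray(p_mask, dtype=float)
    keep = (rng.random(p_mask.shape) >= p_mask).astype(float)
    return keep, np.asarray(X, dtype=float) * keep


def edge_weights(F: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Per-edge importance M_L[(i,j)] = log((F[i] + F[j]) / 2 + eps).

    The log damps the influence of very high-centrality hubs; eps guards
    isolated endpoints with zero centrality.
    """
    F = np.asarray(F, dtype=float)
    edges = np.asarray(edges, dtype=int)
    if edges.size == 0:
        return np.zeros(0)
    return np.log((F[edges[:, 0]] + F[edges[:, 1]]) / 2.0 + _EPS)


def sample_edge_pruning(edges: np.ndarray, p_prune: np.ndarray, n_nodes: int,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Keep each undirected edge with probability 1 - p_prune (one coin per
    edge, applied to both directions).  Returns (retained edges, A')."""
    edges = np.asarray(edges, dtype=int).reshape(-1, 2)
    p_prune = np.asarray(p_prune, dtype=float)
    keep = rng.random(len(edges)) >= p_prune
    retained = edges[keep]
    A = np.zeros((n_nodes, n_nodes))
    if len(retained):
        A[retained[:, 0], retained[:, 1]] = 1.0
        A[retained[:, 1], retained[:, 0]] = 1.0
    return retained, A


def centrality_profile(G: HeteroGraph, X: np.ndarray | None = None) -> CentralityProfile:
    """Centrality and derived mask/prune weights for one graph.

    X defaults to the graph's own features; passing the current (learned)
    feature values lets the profile track training.
    """
    if X is None:
        X = G.X.data if hasattr(G.X, "data") else np.asarray(G.X)
    F = eigenvector_centrality(G.A)
    edges = G.edge_list()
    return CentralityProfile(F=F, M_N=feature_mask_weights(X, F),
                             M_L=edge_weights(F, edges), edges=edges)


def morph(G: HeteroGraph, params: AugmentParams, seed: int,
          profile: CentralityProfile | None = None) -> AugmentedViews:
    """Generate the two stochastic views of a graph (one iteration).

    Composes centrality -> weights -> adaptive probabilities -> Bernoulli
    sampling.  The profile may be precomputed and reused while the adjacency
    is unchanged; the Bernoulli draws are fresh for every call, keyed by
    ``seed``.
    """
    if G.n_nodes == 0:
        raise ValueError("cannot augment an empty graph")
    if profile is None:
        profile = centrality_profile(G)
    X = G.X.data if hasattr(G.X, "data") else np.asarray(G.X)
    rng = np.random.default_rng(seed)
    p_mask = adaptive_probabilities(profile.M_N, params.rho_n, params.t_n)
    keep, X_masked = sample_feature_mask(X, p_mask, rng)
    p_prune = adaptive_probabilities(profile.M_L, params.rho_l, params.t_l)
    retained, A_pruned = sample_edge_pruning(profile.edges, p_prune,
                                             G.n_nodes, rng)
    G_N = HeteroGraph(X_masked, G.A.copy(), G.m, G.n, polarity=G.polarity)
    G_L = HeteroGraph(X, A_pruned, G.m, G.n, polarity=G.polarity)
    return AugmentedViews(G_N=G_N, G_L=G_L, mask=keep, retained_edges=retained)
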