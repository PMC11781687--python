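"""Fused node features and bipartite heterogeneous graph assembly.

Cell lines and drugs live in different feature spaces (multi-omics vectors
vs fingerprint bits), so both are projected to a shared dimension.  Each
entity gets two complementary representations that are summed elementwise:

* linear features — a learnable projection, row-scaled by normalization
  coefficients derived from the response matrix degree structure; and
* nonlinear features — one round of graph propagation over an intra-entity
  similarity graph (Pearson top-k), which injects neighborhood structure.

The fused features become the nodes of a heterogeneous bipartite graph
whose edges are the *sensitive* cell-line/drug pairs of the training fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from ._tensor import Tensor, as_tensor, concat_rows
from .data_ingest import ResponseTable

__all__ = [
    "FeatureBundle", "SimilarityGraph", "HeteroGraph",
    "linear_transform", "normalization_coeffs", "linear_features",
    "similarity_graph", "nonlinear_features", "assemble_hetero_graph",
]


def _plain(out: Tensor, *inputs):
    """Return a bare array unless some input was on the autodiff tape."""
    if any(isinstance(x, Tensor) for x in inputs):
        return out
    return out.data


@dataclass
class SimilarityGraph:
    """Intra-entity similarity graph (cells or drugs)."""
    entity: Literal["cell", "drug"]
    node_features: np.ndarray
    adjacency: np.ndarray  # binary, symmetric, zero diagonal


@dataclass
class FeatureBundle:
    """Linear + nonlinear features per entity; fused additively."""
    LF_cell: object
    LF_drug: object
    NLF_cell: object
    NLF_drug: object

    @property
    def X_C(self):
        return self.LF_cell + self.NLF_cell

    @property
    def X_D(self):
        return self.LF_drug + self.NLF_drug

    @property
    def X_CD(self):
        if isinstance(self.X_C, Tensor) or isinstance(self.X_D, Tensor):
            return concat_rows(as_tensor(self.X_C), as_tensor(self.X_D))
        return np.concatenate([self.X_C, self.X_D], axis=0)


@dataclass
class HeteroGraph:
    """Block-bipartite graph over m cell nodes followed by n drug nodes."""
    X: object               # (m+n) x d node features (array or Tensor)
    A: np.ndarray           # (m+n) x (m+n) binary symmetric adjacency
    m: int
    n: int
    polarity: Literal["sensitivity", "resistance"] = "sensitivity"

    def __post_init__(self):
        N = self.m + self.n
        if self.A.shape != (N, N):
            raise ValueError("adjacency shape does not match m+n")

    @property
    def n_nodes(self) -> int:
        return self.m + self.n

    def edge_list(self) -> np.ndarray:
        """Undirected edges as (i, j) with i < j."""
        iu, ju = np.nonzero(np.triu(self.A, k=1))
        return np.column_stack([iu, ju])


def linear_transform(C, D, W_c, W_d):
    """Project cell and drug features to the shared dimension: E = X @ W."""
    Ct, Dt, Wct, Wdt = map(as_tensor, (C, D, W_c, W_d))
    if Ct.shape[1] != Wct.shape[0] or Dt.shape[1] != Wdt.shape[0]:
        raise ValueError("projection weight dimensions do not conform")
    return _plain(Ct @ Wct, C, W_c), _plain(Dt @ Wdt, D, W_d)


def normalization_coeffs(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Diagonal normalization coefficients from the response matrix.

    For each cell line (row) and drug (column), the coefficient is
    1/(degree + 1) + 1 where degree counts sensitive associations; entries
    therefore lie in (1, 2].  Returned as the diagonal vectors.
    """
    A = np.asarray(A, dtype=float)
    n_c = 1.0 / (A.sum(axis=1) + 1.0) + 1.0
    n_d = 1.0 / (A.sum(axis=0) + 1.0) + 1.0
    return n_c, n_d


def linear_features(E_c, E_d, n_c, n_d, omega1, omega2):
    """Row-scale projected features: LF = omega * diag(n) @ E."""
    Ect, Edt = as_tensor(E_c), as_tensor(E_d)
    o1, o2 = as_tensor(omega1), as_tensor(omega2)
    nc = as_tensor(np.asarray(n_c, dtype=float).reshape(-1, 1))
    nd = as_tensor(np.asarray(n_d, dtype=float).reshape(-1, 1))
    lf_c = o1 * (nc * Ect)
    lf_d = o2 * (nd * Edt)
    return _plain(lf_c, E_c, omega1), _plain(lf_d, E_d, omega2)


def similarity_graph(features: np.ndarray, k: int = 10,
                     entity: str = "cell") -> SimilarityGraph:
    """Pearson top-k similarity graph over rows of a feature matrix.

    Each row keeps edges to its k most correlated other rows; the adjacency
    is symmetrized by max (union of the directed top-k picks) and binarized.
    Constant rows have undefined correlations, which are set to 0.
    """
    X = np.asarray(features, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows for a similarity graph")
    if not 1 <= k < X.shape[0]:
        raise ValueError("k must satisfy 1 <= k < number of rows")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(X)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, -np.inf)
    A = np.zeros_like(corr)
    topk = np.argpartition(-corr, k - 1, axis=1)[:, :k]
    rows = np.repeat(np.arange(X.shape[0]), k)
    A[rows, topk.ravel()] = 1.0
    A = np.maximum(A, A.T)
    np.fill_diagonal(A, 0.0)
    return SimilarityGraph(entity, X, A)


def nonlinear_features(sim: SimilarityGraph, W, slope: float = 0.2):
    """One-hop graph propagation over the similarity graph (GCN, K=1).

    Computes act(A_hat @ X @ W) where A_hat is the symmetric-normalized
    adjacency with self-loops (see :func:`asgcl.contrastive.propagate_layer`).
    """
    from .contrastive import propagate_layer
    return propagate_layer(sim.node_features, sim.adjacency, W, slope=slope)


def assemble_hetero_graph(bundle: FeatureBundle, responses: ResponseTable,
                          train_mask: np.ndarray) -> HeteroGraph:
    """Build the sensitivity graph from fused features and training labels.

    Edges connect cell node i to drug node (m + j) exactly where the pair is
    observed, in the training mask, and labeled sensitive.  Labeled negatives
    and all held-out pairs never become edges (they feed only the supervised
    loss), which keeps test folds out of the message-passing structure.
    """
    X_C, X_D = bundle.X_C, bundle.X_D
    d_c = X_C.shape[1] if not isinstance(X_C, Tensor) else X_C.data.shape[1]
    d_d = X_D.shape[1] if not isinstance(X_D, Tensor) else X_D.data.shape[1]
    if d_c != d_d:
        raise ValueError("cell and drug fused feature dimensions differ")
    m, n = responses.shape
    pos = (responses.labels == 1) & responses.observed & np.asarray(train_mask, bool)
    if not pos.any():
        warnings.warn("no training-fold positives: sensitivity graph is empty")
    A = np.zeros((m + n, m + n))
    ci, dj = np.nonzero(pos)
    A[ci, m + dj] = 1.0
    A[m + dj, ci] = 1.0
    return HeteroGraph(bundle.X_CD, A, m, n, polarity="sensitivity")
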