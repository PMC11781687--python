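"""Training loop, stratified cross-validation, metrics and ranking.

Observed cell-line/drug pairs are split into stratified folds; per fold the
sensitivity graph is rebuilt from training positives only (held-out pairs
never enter the adjacency or any loss term), a 10% stratified carve-out of
the training pairs drives early stopping on validation AUC, and the test
fold is scored once with the best weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, train_test_split

from .contrastive import (EncoderConfig, LossWeights, graph_contrastive_loss,
                          node_contrastive_loss, normalized_adjacency,
                          readout_summary, supervised_loss, total_loss)
from ._tensor import Adam
from .data_ingest import Dataset, ResponseTable
from .graphmorpher import (AugmentParams, CentralityProfile, edge_weights,
                           eigenvector_centrality, feature_mask_weights,
                           invert_adjacency, morph)
from .model import ASGCLModel
from .subspace import HeteroGraph, normalization_coeffs, similarity_graph

__all__ = [
    "TrainConfig", "FoldSplit", "MetricsReport", "RankedPredictions",
    "TrainedModel", "stratified_folds", "train_one_fold", "confusion_metrics",
    "roc_auc", "average_precision", "metrics_report", "cross_validate",
    "predict_missing_ranked",
]


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    Defaults follow the reference setting: Adam at 5e-4, stratified 5-fold
    CV, loss weights 0.4/0.4/0.2, augmentation (0.2, 0.3) with caps
    (0.3, 0.4), shared dimension 224 and a K=1 GCN encoder; early stopping
    (unspecified in the reference) uses patience 50 within 1000 epochs on a
    10% validation carve-out.
    """
    learning_rate: float = 5e-4
    epochs: int = 1000
    patience: int = 50
    folds: int = 5
    seed: int = 0
    d_shared: int = 224
    sim_k: int = 10
    val_fraction: float = 0.1
    use_resistance: bool = True
    contrast_resistance_views: bool = True
    augment: AugmentParams = field(default_factory=AugmentParams)
    loss_weights: LossWeights = field(default_factory=LossWeights)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class FoldSplit:
    """Disjoint train/test pair lists; columns (cell, drug, label)."""
    fold_id: int
    train_pairs: np.ndarray
    test_pairs: np.ndarray


@dataclass
class MetricsReport:
    auc: float
    ap: float
    acc: float
    f1: float
    mcc: float
    precision: float
    recall: float
    confusion: tuple[int, int, int, int]  # TP, TN, FP, FN

    def as_dict(self) -> dict:
        return {"auc": self.auc, "ap": self.ap, "acc": self.acc,
                "f1": self.f1, "mcc": self.mcc, "precision": self.precision,
                "recall": self.recall}


@dataclass
class RankedPredictions:
    """Per-drug predicted scores over unobserved cell lines, ranked."""
    scores: dict      # drug id -> np.ndarray of predicted probabilities
    medians: dict     # drug id -> median score
    ranking: list     # drug ids, highest median (most sensitive) first


# ---------------------------------------------------------------------------
# splits and metrics
# ---------------------------------------------------------------------------

def stratified_folds(responses: ResponseTable, k: int, seed: int = 0) -> list[FoldSplit]:
    """Label-stratified k-fold partition of all observed pairs."""
    pairs = responses.observed_pairs()
    labels = pairs[:, 2]
    for cls in (0, 1):
        if (labels == cls).sum() < k:
            raise ValueError(f"class {cls} has fewer than {k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [FoldSplit(i, pairs[tr], pairs[te])
            for i, (tr, te) in enumerate(skf.split(pairs, labels))]


def confusion_metrics(labels, predictions) -> MetricsReport:
    """Confusion-matrix metrics from binary predictions.

    MCC is defined as 0 whenever a denominator factor vanishes.  AUC/AP are
    filled with NaN; use :func:`metrics_report` for score-based metrics.
    """
    y = np.asarray(labels, int).ravel()
    p = np.asarray(predictions, int).ravel()
    if y.size == 0:
        raise ValueError("empty input")
    tp = int(((y == 1) & (p == 1)).sum())
    tn = int(((y == 0) & (p == 0)).sum())
    fp = int(((y == 0) & (p == 1)).sum())
    fn = int(((y == 1) & (p == 0)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    acc = (tp + tn) / y.size
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return MetricsReport(auc=np.nan, ap=np.nan, acc=acc, f1=f1, mcc=float(mcc),
                         precision=precision, recall=recall,
                         confusion=(tp, tn, fp, fn))


def roc_auc(labels, scores) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) with ties counted 1/2."""
    y = np.asarray(labels, int).ravel()
    s = np.asarray(scores, float).ravel()
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for AUC")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def average_precision(labels, scores) -> float:
    """Step-wise AP: sum of (R_k - R_{k-1}) * P_k over the sorted ranking."""
    y = np.asarray(labels, int).ravel()
    s = np.asarray(scores, float).ravel()
    n_pos = int((y == 1).sum())
    if n_pos == 0:
        raise ValueError("average precision needs at least one positive")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    tp_cum = np.cumsum(y_sorted)
    precision = tp_cum / np.arange(1, y.size + 1)
    recall_step = y_sorted / n_pos
    return float((precision * recall_step).sum())


def metrics_report(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Full report: AUC/AP from scores, the rest at the decision threshold."""
    rep = confusion_metrics(labels, np.asarray(scores, float) >= threshold)
    rep.auc = roc_auc(labels, scores)
    rep.ap = average_precision(labels, scores)
    return rep


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A trained fold: best weights plus the embeddings they induce."""
    model: ASGCLModel
    H: np.ndarray          # node embeddings from the training-fold graph
    m: int
    n: int

    def score_pairs(self, pairs) -> np.ndarray:
        return self.model.score_pairs(self.H, np.asarray(pairs, int)[:, :2],
                                      self.m, self.n)


class _FoldContext:
    """Per-fold constants: features, similarity graphs, adjacencies."""

    def __init__(self, dataset: Dataset, train_pairs: np.ndarray,
                 config: TrainConfig):
        m, n = dataset.responses.shape
        self.m, self.n = m, n
        self.C = dataset.cell_features()
        self.D = dataset.drugs.values
        k_cell = min(config.sim_k, m - 1)
        k_drug = min(config.sim_k, n - 1)
        sim_c = similarity_graph(self.C, k_cell, entity="cell")
        sim_d = similarity_graph(self.D, k_drug, entity="drug")
        # propagated raw features are constant: precompute A_hat @ X
        self.AC_prop = normalized_adjacency(sim_c.adjacency) @ self.C
        self.AD_prop = normalized_adjacency(sim_d.adjacency) @ self.D

        A_lab = np.zeros((m, n))
        pos = train_pairs[train_pairs[:, 2] == 1]
        A_lab[pos[:, 0], pos[:, 1]] = 1.0
        self.n_c, self.n_d = normalization_coeffs(A_lab)

        placeholder = np.zeros((m + n, 1))  # features attached per epoch
        A = np.zeros((m + n, m + n))
        A[:m, m:] = A_lab
        A[m:, :m] = A_lab.T
        self.G_sen = HeteroGraph(placeholder, A, m, n, "sensitivity")
        self.G_res = invert_adjacency(self.G_sen)
        self.A_hat_sen = normalized_adjacency(self.G_sen.A)
        self.A_hat_res = normalized_adjacency(self.G_res.A)
        # centrality depends only on the (fixed) fold adjacency
        self._static = {}
        for name, G in (("sen", self.G_sen), ("res", self.G_res)):
            F = eigenvector_centrality(G.A)
            edges = G.edge_list()
            self._static[name] = (F, edges, edge_weights(F, edges))

    def profile(self, name: str, X_now: np.ndarray) -> CentralityProfile:
        F, edges, M_L = self._static[name]
        return CentralityProfile(F=F, M_N=feature_mask_weights(X_now, F),
                                 M_L=M_L, edges=edges)


def _contrastive_pair(model, ctx, name: str, X_CD, params: AugmentParams,
                      seed: int, tau: float):
    """Node-level InfoNCE between the masked and pruned view of one graph."""
    G = ctx.G_sen if name == "sen" else ctx.G_res
    A_hat = ctx.A_hat_sen if name == "sen" else ctx.A_hat_res
    prof = ctx.profile(name, X_CD.data)
    views = morph(G, params, seed, profile=prof)
    X_masked = X_CD * views.mask[None, :]
    H_N = model.encode(X_masked, A_hat)
    H_L = model.encode(X_CD, normalized_adjacency(views.G_L.A))
    return node_contrastive_loss(model.project(H_N), model.project(H_L), tau)


def train_one_fold(dataset: Dataset, split: FoldSplit,
                   config: TrainConfig) -> tuple[TrainedModel, dict]:
    """Train on one fold with early stopping; returns best weights + history.

    Each epoch rebuilds the augmented views with a fresh epoch-derived seed,
    computes the weighted total loss on training pairs only, and takes one
    Adam step.  Raises on a non-finite loss with epoch diagnostics.
    """
    w = config.loss_weights
    contrastive_on = w.beta > 0 or w.gamma > 0
    rng_seed = config.seed * 1000 + split.fold_id

    # 10% stratified validation carve-out for early stopping
    tr_idx, val_idx = train_test_split(
        np.arange(len(split.train_pairs)), test_size=config.val_fraction,
        random_state=rng_seed % (2 ** 31), stratify=split.train_pairs[:, 2])
    train_pairs = split.train_pairs[tr_idx]
    val_pairs = split.train_pairs[val_idx]

    ctx = _FoldContext(dataset, train_pairs, config)
    m, n = ctx.m, ctx.n
    # leakage guards: held-out and validation pairs never enter the adjacency
    for held in (split.test_pairs, val_pairs):
        assert not ctx.G_sen.A[held[:, 0], m + held[:, 1]].any(), \
            "held-out pair leaked into the training adjacency"

    model = ASGCLModel(ctx.C.shape[1], ctx.D.shape[1], config.d_shared,
                       config.encoder, seed=rng_seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    y_train = train_pairs[:, 2].astype(float)
    tau = config.encoder.tau

    history = {"loss": [], "l_sup": [], "l_nod": [], "l_gra": [], "val_auc": []}
    best = {"auc": -np.inf, "state": None, "H": None, "epoch": -1}

    for epoch in range(config.epochs):
        bundle = model.fuse_features(ctx.C, ctx.D, ctx.n_c, ctx.n_d,
                                     ctx.AC_prop, ctx.AD_prop)
        X_CD = bundle.X_CD
        H_sen = model.encode(X_CD, ctx.A_hat_sen)
        scores = model.score_pairs(H_sen, train_pairs[:, :2], m, n)
        l_sup = supervised_loss(scores, y_train)

        if contrastive_on:
            ep_seed = (config.seed + epoch) % (2 ** 31)
            l_nod = _contrastive_pair(model, ctx, "sen", X_CD, config.augment,
                                      ep_seed, tau)
            if config.use_resistance and config.contrast_resistance_views:
                l_nod_res = _contrastive_pair(model, ctx, "res", X_CD,
                                              config.augment,
                                              (ep_seed + 7919) % (2 ** 31), tau)
                l_nod = (l_nod + l_nod_res) * 0.5
            if config.use_resistance:
                H_res = model.encode(X_CD, ctx.A_hat_res)
                V = readout_summary(H_sen)
                U = readout_summary(H_res)
                l_gra = graph_contrastive_loss(H_sen, H_res, V, U, model.W_V)
            else:
                l_gra = l_sup * 0.0
        else:
            l_nod = l_sup * 0.0
            l_gra = l_sup * 0.0

        loss = total_loss(l_sup, l_nod, l_gra, w)
        if not np.isfinite(loss.data):
            raise RuntimeError(
                f"non-finite loss at epoch {epoch}: sup={float(l_sup.data):.4g} "
                f"nod={float(l_nod.data):.4g} gra={float(l_gra.data):.4g}")
        opt.zero_grad()
        loss.backward()
        opt.step()

        val_scores = model.score_pairs(H_sen.data, val_pairs[:, :2], m, n)
        try:
            val_auc = roc_auc(val_pairs[:, 2], val_scores)
        except ValueError:
            val_auc = 0.5
        history["loss"].append(float(loss.data))
        history["l_sup"].append(float(l_sup.data))
        history["l_nod"].append(float(l_nod.data))
        history["l_gra"].append(float(l_gra.data))
        history["val_auc"].append(val_auc)

        if val_auc > best["auc"]:
            best.update(auc=val_auc, state=model.state(), H=H_sen.data.copy(),
                        epoch=epoch)
        elif epoch - best["epoch"] >= config.patience:
            break

    model.load_state(best["state"])
    history["best_epoch"] = best["epoch"]
    return TrainedModel(model, best["H"], m, n), history


def cross_validate(dataset: Dataset, config: TrainConfig) -> dict:
    """Stratified k-fold CV; per-fold reports plus mean/sd aggregation."""
    splits = stratified_folds(dataset.responses, config.folds, config.seed)
    folds = []
    for split in splits:
        trained, history = train_one_fold(dataset, split, config)
        scores = trained.score_pairs(split.test_pairs)
        rep = metrics_report(split.test_pairs[:, 2], scores)
        folds.append(rep)
    keys = ["auc", "ap", "acc", "f1", "mcc", "precision", "recall"]
    stacked = {k: np.array([getattr(r, k) for r in folds]) for k in keys}
    return {"folds": folds,
            "mean": {k: float(v.mean()) for k, v in stacked.items()},
            "sd": {k: float(v.std()) for k, v in stacked.items()}}


def predict_missing_ranked(trained: TrainedModel,
                           dataset: Dataset) -> RankedPredictions:
    """Score unobserved pairs; rank drugs by median predicted sensitivity.

    Only unobserved (cell, drug) pairs are scored; drugs are sorted with the
    highest median predicted sensitivity first.
    """
    resp = dataset.responses
    ci, dj = np.nonzero(~resp.observed)
    if ci.size == 0:
        raise ValueError("no unobserved pairs to predict")
    scores = trained.score_pairs(np.column_stack([ci, dj]))
    per_drug, medians = {}, {}
    for j, drug in enumerate(resp.drug_ids):
        s = scores[dj == j]
        if s.size:
            per_drug[drug] = s
            medians[drug] = float(np.median(s))
    ranking = sorted(medians, key=lambda d: -medians[d])
    return RankedPredictions(scores=per_drug, medians=medians, ranking=ranking)
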