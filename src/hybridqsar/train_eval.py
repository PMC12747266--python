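"""Training loop and evaluation metrics for the hybrid regressor.

Optimization: Adam (lr 1e-3, L2 weight decay 1e-5) on a smooth-L1 (Huber)
loss over log10 IC50, batch size 32, 300 epochs by default, with
per-target oversampling of the training set drawn once before training.
Metrics: R^2, RMSE and MAE on the log scale, overall and per target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

from . import nn
from ._autodiff import Tensor, no_grad
from .data_pipeline import CleanDataset, oversample_by_target
from .featurize import (AtomVocab, MolecularGraph, Normalizer,
                        descriptor_vector, fit_normalizer, smiles_to_graph)
from .model import GraphBatch, HybridIC50Model


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    weight_decay: float = 1e-5
    batch_size: int = 32
    epochs: int = 300
    huber_beta: float = 1.0
    seed: int = 42
    oversample: bool = True
    init_output_bias: bool = True   # start output bias at the train-label mean
    precise_bn: bool = True         # recalibrate BN stats after each epoch

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("rates and sizes must be positive")
        if self.huber_beta <= 0:
            raise ValueError("huber_beta must be positive")


@dataclass
class Metrics:
    group: str
    r2: float | None
    rmse: float
    mae: float
    n: int
    r2_undefined: bool = False

    def to_dict(self) -> dict:
        return {"group": self.group, "r2": self.r2, "rmse": self.rmse,
                "mae": self.mae, "n": self.n,
                "r2_undefined": self.r2_undefined}


def smooth_l1(pred: float, truth: float, beta: float = 1.0) -> float:
    """Scalar smooth-L1 (Huber): quadratic for |d| < beta, linear beyond."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    d = abs(pred - truth)
    return 0.5 * d * d / beta if d < beta else d - 0.5 * beta


def smooth_l1_loss(pred: Tensor, truth: np.ndarray, beta: float = 1.0) -> Tensor:
    """Mean smooth-L1 over a batch, differentiable w.r.t. predictions.

    Written as 0.5 d^2/beta on |d|<beta and |d| - beta/2 outside via a
    mask decomposition; the two pieces meet smoothly at |d| = beta.
    """
    d = pred - Tensor(truth)
    absd = np.abs(d.data)
    quad = np.asarray(absd < beta, dtype=np.float64)
    sign = np.sign(d.data)
    quadratic = d * d * Tensor(quad * 0.5 / beta)
    # linear part: sign*d - beta/2, gated by (1 - quad)
    linear = (d * Tensor(sign) - 0.5 * beta) * Tensor(1.0 - quad)
    return (quadratic + linear).mean()


def evaluate(preds: Iterable[float], truths: Iterable[float],
             groups: Iterable[str] | None = None) -> list[Metrics]:
    """R^2 / RMSE / MAE overall and per target group (groups with >= 2 rows).

    R^2 uses each evaluated group's own truth mean for the total sum of
    squares. A group whose truths have zero variance gets a flagged record
    (``r2_undefined``) instead of a number.
    """
    preds = np.asarray(list(preds), dtype=np.float64)
    truths = np.asarray(list(truths), dtype=np.float64)
    if preds.shape != truths.shape:
        raise ValueError("preds and truths must have equal length")
    if len(preds) < 2:
        raise ValueError("need at least 2 samples to evaluate")

    def one(group: str, p: np.ndarray, t: np.ndarray) -> Metrics:
        rmse = float(np.sqrt(mean_squared_error(t, p)))
        mae = float(mean_absolute_error(t, p))
        if np.allclose(t, t[0]):
            return Metrics(group=group, r2=None, rmse=rmse, mae=mae,
                           n=len(p), r2_undefined=True)
        return Metrics(group=group, r2=float(r2_score(t, p)), rmse=rmse,
                       mae=mae, n=len(p))

    out = [one("overall", preds, truths)]
    if groups is not None:
        groups = np.asarray(list(groups))
        if groups.shape != preds.shape:
            raise ValueError("groups must match preds length")
        for g in sorted(set(groups.tolist())):
            mask = groups == g
            if mask.sum() >= 2:
                out.append(one(g, preds[mask], truths[mask]))
    return out


class Adam:
    """Adam with decoupled-from-loss L2 weight decay added to the gradient."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


@dataclass
class FeaturizedDataset:
    """Model-ready arrays for a set of clean samples."""

    graphs: list[MolecularGraph]
    descriptors: np.ndarray        # (n, 544), normalized
    mol_sizes: np.ndarray          # (n,)
    labels: np.ndarray             # (n,) log10 IC50
    target_ids: list[str]

    def __len__(self) -> int:
        return len(self.graphs)

    def subset(self, idx: np.ndarray) -> "FeaturizedDataset":
        return FeaturizedDataset(
            graphs=[self.graphs[i] for i in idx],
            descriptors=self.descriptors[idx],
            mol_sizes=self.mol_sizes[idx],
            labels=self.labels[idx],
            target_ids=[self.target_ids[i] for i in idx])


def featurize_dataset(dataset: CleanDataset, vocab: AtomVocab,
                      normalizer: Normalizer | None = None
                      ) -> tuple[FeaturizedDataset, Normalizer]:
    """Featurize clean samples; fit the normalizer here iff none is given.

    Pass ``normalizer=None`` for the training set (statistics are fitted on
    it) and the fitted normalizer for test/prediction sets, so evaluation
    inputs always use train statistics.
    """
    smiles = [s.canonical_smiles for s in dataset.samples]
    graphs = [smiles_to_graph(s, vocab) for s in smiles]
    raw = np.vstack([descriptor_vector(s) for s in smiles])
    if normalizer is None:
        normalizer = fit_normalizer(raw)
    desc = normalizer.apply(raw)
    return FeaturizedDataset(
        graphs=graphs,
        descriptors=desc,
        mol_sizes=np.array([g.mol_size for g in graphs], dtype=np.float64),
        labels=np.array([s.log_ic50 for s in dataset.samples]),
        target_ids=[s.target_id for s in dataset.samples],
    ), normalizer


FEATURE_ARCHIVE_VERSION = 1


def save_featurized(path, data: FeaturizedDataset, vocab: AtomVocab,
                    normalizer: Normalizer) -> None:
    """Write a featurized dataset as one versioned .npz archive.

    Ragged per-molecule node/edge arrays are stored concatenated with
    offset tables; the vocabulary and normalizer ride along as JSON so the
    archive is self-contained.
    """
    import json

    node_counts = np.array([g.n_nodes for g in data.graphs])
    edge_counts = np.array([g.edge_index.shape[1] for g in data.graphs])
    meta = {"format_version": FEATURE_ARCHIVE_VERSION,
            "vocab": vocab.to_dict(), "normalizer": normalizer.to_dict()}
    np.savez(
        path,
        meta=np.array(json.dumps(meta)),
        node_counts=node_counts,
        edge_counts=edge_counts,
        node_vocab_ids=np.concatenate(
            [g.node_vocab_ids for g in data.graphs]),
        node_features=np.vstack([g.node_features for g in data.graphs]),
        edge_index=np.hstack([g.edge_index for g in data.graphs])
        if edge_counts.sum() else np.zeros((2, 0), dtype=np.int64),
        edge_features=np.vstack([g.edge_features for g in data.graphs]),
        descriptors=data.descriptors,
        mol_sizes=data.mol_sizes,
        labels=data.labels,
        target_ids=np.array(data.target_ids, dtype="U"),
    )


def load_featurized(path) -> tuple[FeaturizedDataset, AtomVocab, Normalizer]:
    """Read an archive written by :func:`save_featurized`."""
    import json

    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        if meta["format_version"] != FEATURE_ARCHIVE_VERSION:
            raise ValueError(
                f"unsupported feature archive version "
                f"{meta['format_version']}")
        node_counts = z["node_counts"]
        edge_counts = z["edge_counts"]
        node_splits = np.cumsum(node_counts)[:-1]
        edge_splits = np.cumsum(edge_counts)[:-1]
        vocab_ids = np.split(z["node_vocab_ids"], node_splits)
        node_feats = np.split(z["node_features"], node_splits)
        edge_idx = np.split(z["edge_index"], edge_splits, axis=1)
        edge_feats = np.split(z["edge_features"], edge_splits)
        mol_sizes = z["mol_sizes"]
        graphs = [MolecularGraph(
            n_nodes=int(node_counts[i]),
            node_vocab_ids=vocab_ids[i],
            node_features=node_feats[i],
            edge_index=edge_idx[i].astype(np.int64),
            edge_features=edge_feats[i],
            mol_size=int(mol_sizes[i]),
        ) for i in range(len(node_counts))]
        data = FeaturizedDataset(
            graphs=graphs,
            descriptors=z["descriptors"],
            mol_sizes=mol_sizes.astype(np.float64),
            labels=z["labels"],
            target_ids=[str(t) for t in z["target_ids"]])
        return (data, AtomVocab.from_dict(meta["vocab"]),
                Normalizer.from_dict(meta["normalizer"]))


def predict_dataset(model: HybridIC50Model, data: FeaturizedDataset,
                    batch_size: int = 256) -> np.ndarray:
    """Eval-mode predictions for a featurized dataset."""
    was_training = model.training
    model.eval()
    preds = []
    try:
        with no_grad():
            for start in range(0, len(data), batch_size):
                idx = np.arange(start, min(start + batch_size, len(data)))
                sub = data.subset(idx)
                preds.append(model(GraphBatch.collate(sub.graphs),
                                   sub.descriptors, sub.mol_sizes).data)
    finally:
        if was_training:
            model.train()
    return np.concatenate(preds)


def recalibrate_batchnorm(model: HybridIC50Model,
                          data: FeaturizedDataset) -> None:
    """Recompute all batch-norm running statistics in one dropout-free pass.

    Running statistics accumulated during training average activations seen
    under dropout noise; this "precise" recalibration replaces them with the
    statistics of the deterministic network on the full training set, so
    eval-mode predictions match the network actually optimized.
    """
    dropouts = [m for m in model.modules() if isinstance(m, nn.Dropout)]
    norms = [m for m in model.modules() if isinstance(m, nn.BatchNorm1d)]
    saved_p = [d.p for d in dropouts]
    saved_mom = [m.momentum for m in norms]
    for d in dropouts:
        d.p = 0.0
    for m in norms:
        m.momentum = 1.0
    was_training = model.training
    model.train()
    try:
        with no_grad():
            model(GraphBatch.collate(data.graphs), data.descriptors,
                  data.mol_sizes)
    finally:
        for d, p in zip(dropouts, saved_p):
            d.p = p
        for m, mom in zip(norms, saved_mom):
            m.momentum = mom
        if not was_training:
            model.eval()


def train(model: HybridIC50Model, train_data: FeaturizedDataset,
          test_data: FeaturizedDataset | None, tcfg: TrainConfig,
          verbose: bool = False) -> pd.DataFrame:
    """Seeded mini-batch training; returns the per-epoch history frame.

    Oversampling (when enabled) is applied by the caller on the clean
    dataset before featurization, or here is a no-op — see
    :func:`train_on_clean` for the full pipeline. History records train/test
    loss, R^2 and RMSE each epoch; no model selection uses the test curve.
    """
    if len(train_data) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(tcfg.seed)
    optimizer = Adam(model.parameters(), lr=tcfg.learning_rate,
                     weight_decay=tcfg.weight_decay)
    if tcfg.init_output_bias:
        model.out_linear.bias.data[:] = float(train_data.labels.mean())
    history = []
    n = len(train_data)
    for epoch in range(tcfg.epochs):
        model.train()
        perm = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, tcfg.batch_size):
            idx = perm[start:start + tcfg.batch_size]
            if len(idx) < 2:
                continue  # batch norm needs >= 2 samples
            sub = train_data.subset(idx)
            preds = model(GraphBatch.collate(sub.graphs), sub.descriptors,
                          sub.mol_sizes)
            loss = smooth_l1_loss(preds, sub.labels, tcfg.huber_beta)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        if tcfg.precise_bn:
            recalibrate_batchnorm(model, train_data)
        row = {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1)}
        train_preds = predict_dataset(model, train_data)
        row["train_rmse"] = float(np.sqrt(np.mean(
            (train_preds - train_data.labels) ** 2)))
        row["train_r2"] = _safe_r2(train_data.labels, train_preds)
        if test_data is not None and len(test_data) >= 2:
            test_preds = predict_dataset(model, test_data)
            row["test_loss"] = float(np.mean([
                smooth_l1(p, t, tcfg.huber_beta)
                for p, t in zip(test_preds, test_data.labels)]))
            row["test_rmse"] = float(np.sqrt(np.mean(
                (test_preds - test_data.labels) ** 2)))
            row["test_r2"] = _safe_r2(test_data.labels, test_preds)
        history.append(row)
        if verbose and (epoch % 10 == 0 or epoch == tcfg.epochs - 1):
            print(f"epoch {epoch:4d}  " +
                  "  ".join(f"{k}={v:.4f}" for k, v in row.items()
                            if k != "epoch"))
    return pd.DataFrame(history)


def _safe_r2(truths: np.ndarray, preds: np.ndarray) -> float:
    if np.allclose(truths, truths[0]):
        return float("nan")
    return float(r2_score(truths, preds))


def train_on_clean(model: HybridIC50Model, train_set: CleanDataset,
                   test_set: CleanDataset | None, tcfg: TrainConfig,
                   vocab: AtomVocab, verbose: bool = False
                   ) -> tuple[pd.DataFrame, Normalizer, FeaturizedDataset,
                              FeaturizedDataset | None]:
    """Full path from clean datasets: oversample, featurize, fit, train.

    The normalizer is fitted on the original (pre-oversampling) training
    set; oversampled duplicates reuse those statistics.
    """
    normalizer = fit_normalizer(
        np.vstack([descriptor_vector(s.canonical_smiles)
                   for s in train_set.samples]))
    if tcfg.oversample and len(train_set.targets()) > 1:
        train_set = oversample_by_target(train_set, seed=tcfg.seed)
    train_data, _ = featurize_dataset(train_set, vocab, normalizer)
    test_data = None
    if test_set is not None and len(test_set):
        test_data, _ = featurize_dataset(test_set, vocab, normalizer)
    history = train(model, train_data, test_data, tcfg, verbose=verbose)
    return history, normalizer, train_data, test_data
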