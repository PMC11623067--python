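"""Learning protocol: Glorot-uniform init, Adam, stratified k-fold loop with
early stopping on validation accuracy and cross-fold weight carryover.

Hyper-parameter defaults follow the published configuration: Adam with
learning rate 0.001 and epsilon 1e-7, batch size 32, up to 50 epochs per
fold, 10 stratified folds, early-stopping patience 5.  The best weights of
each fold (highest validation accuracy; ties broken by lower validation
loss, then earlier epoch) seed the next fold.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import ArrayDataset, AugmentationConfig, DatasetIndex, augment, stratified_kfold
from .graph import ArchitectureGraph, infer_shapes
from .nn import (
    Adam,
    Params,
    backward_batch,
    check_params,
    clone_params,
    cross_entropy,
    evaluate_batch,
    forward_batch,
)


@dataclass
class TrainingConfig:
    optimizer: str = "adam"
    learning_rate: float = 0.001
    epsilon: float = 1e-7
    batch_size: int = 32
    epochs_per_fold: int = 50
    k_folds: int = 10
    early_stop_metric: str = "val_accuracy"
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.epsilon, self.batch_size,
               self.epochs_per_fold, self.k_folds, self.patience) <= 0:
            raise ValueError("all training hyper-parameters must be positive")
        if self.patience > self.epochs_per_fold:
            raise ValueError("patience must not exceed epochs_per_fold")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass
class FoldHistory:
    train_acc: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0


class EarlyStopping:
    """Patience-based stopping on a maximised metric.

    ``update`` returns True when training should stop: the metric has not
    improved for ``patience`` consecutive epochs.  Ties on the metric break
    toward lower loss, then toward the earlier epoch.
    """

    def __init__(self, patience: int):
        self.patience = patience
        self.best: tuple[float, float] | None = None  # (acc, -loss)
        self.best_epoch = 0
        self.stale = 0

    def update(self, epoch: int, metric: float, loss: float) -> bool:
        key = (metric, -loss)
        if self.best is None or key > self.best:
            self.best = key
            self.best_epoch = epoch
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


def init_weights(graph: ArchitectureGraph, seed: int = 0) -> Params:
    """Glorot-uniform kernels, zero biases, identity batchnorm.

    Conv and dense kernels are drawn from U(-b, b) with
    b = sqrt(6 / (fan_in + fan_out)); batchnorm starts at scale 1 / shift 0
    with running mean 0 and running variance 1.
    """
    rng = np.random.default_rng(seed)
    shapes = infer_shapes(graph)
    params: Params = {}
    for layer in graph.layers:
        if layer.kind == "conv":
            cin = shapes[layer.inputs[0]].channels
            kh, kw, cout = layer.kernel_h, layer.kernel_w, layer.filters
            fan_in, fan_out = kh * kw * cin, kh * kw * cout
            bound = np.sqrt(6.0 / (fan_in + fan_out))
            params[layer.name] = {
                "W": rng.uniform(-bound, bound, size=(kh, kw, cin, cout)),
                "b": np.zeros(cout),
            }
        elif layer.kind == "batchnorm":
            c = shapes[layer.inputs[0]].channels
            params[layer.name] = {
                "gamma": np.ones(c),
                "beta": np.zeros(c),
                "running_mean": np.zeros(c),
                "running_var": np.ones(c),
            }
        elif layer.kind == "dense":
            cin = shapes[layer.inputs[0]].channels
            bound = np.sqrt(6.0 / (cin + layer.filters))
            params[layer.name] = {
                "W": rng.uniform(-bound, bound, size=(cin, layer.filters)),
                "b": np.zeros(layer.filters),
            }
    return params


def _augment_batch(X: np.ndarray, cfg: AugmentationConfig, rng: np.random.Generator) -> np.ndarray:
    return np.stack([augment(img, cfg, rng) for img in X])


def train_fold(
    graph: ArchitectureGraph,
    params: Params,
    data: ArrayDataset,
    train_ids: list[int],
    val_ids: list[int],
    cfg: TrainingConfig,
    rng: np.random.Generator,
    augment_cfg: AugmentationConfig | None = None,
) -> tuple[Params, FoldHistory]:
    """Train one fold; returns the best-validation-epoch parameters.

    One epoch visits every training sample exactly once in ceil(n/batch_size)
    shuffled mini-batches.  Stops early after ``cfg.patience`` epochs without
    a new best validation accuracy and restores the best weights.
    """
    if not train_ids or not val_ids:
        raise ValueError("train and validation id sets must be non-empty")
    if set(train_ids) & set(val_ids):
        raise ValueError("train and validation ids overlap")
    check_params(graph, params)

    Xtr, ytr = data.X[train_ids], data.y[train_ids]
    Xva, yva = data.X[val_ids], data.y[val_ids]
    k = graph.num_classes
    eye = np.eye(k)

    params = clone_params(params)
    opt = Adam(params, lr=cfg.learning_rate, eps=cfg.epsilon)
    stopper = EarlyStopping(cfg.patience)
    history = FoldHistory()
    best_params = clone_params(params)

    n = len(train_ids)
    for epoch in range(1, cfg.epochs_per_fold + 1):
        order = rng.permutation(n)
        losses, accs, weights = [], [], []
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            xb, yb = Xtr[sel], ytr[sel]
            if augment_cfg is not None:
                xb = _augment_batch(xb, augment_cfg, rng)
            probs, caches = forward_batch(graph, params, xb, training=True, rng=rng)
            y1h = eye[yb]
            loss = cross_entropy(probs, y1h)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            grads = backward_batch(graph, params, caches, probs, y1h)
            opt.step(params, grads)
            losses.append(loss)
            accs.append(float((probs.argmax(axis=1) == yb).mean()))
            weights.append(len(sel))
        w = np.asarray(weights, dtype=float)
        history.train_loss.append(float(np.average(losses, weights=w)))
        history.train_acc.append(float(np.average(accs, weights=w)))

        val_loss, val_acc, _ = evaluate_batch(graph, params, Xva, yva)
        history.val_loss.append(val_loss)
        history.val_acc.append(val_acc)

        stop = stopper.update(epoch, val_acc, val_loss)
        if stopper.best_epoch == epoch:  # this epoch set a new best
            best_params = clone_params(params)
        history.best_epoch = stopper.best_epoch
        history.stopped_epoch = epoch
        if stop:
            break
    return best_params, history


def cross_validate(
    graph: ArchitectureGraph,
    index: DatasetIndex,
    cfg: TrainingConfig,
    data: ArrayDataset | None = None,
    augment_cfg: AugmentationConfig | None = None,
    initial_params: Params | None = None,
) -> tuple[Params, list[FoldHistory]]:
    """Stratified k-fold loop with cross-fold weight carryover.

    Fold i+1 resumes from the best weights of fold i; the final fold's best
    weights are returned together with all fold histories.
    """
    if data is None:
        data = ArrayDataset.load(index, size=graph.input_shape.height)
    folds = stratified_kfold(index, k=cfg.k_folds, seed=cfg.seed)
    params = initial_params if initial_params is not None else init_weights(graph, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    histories: list[FoldHistory] = []
    for train_ids, val_ids in folds:
        params, hist = train_fold(
            graph, params, data, train_ids, val_ids, cfg, rng, augment_cfg=augment_cfg
        )
        histories.append(hist)
    return params, histories


def write_training_log(path: str | Path, histories: list[FoldHistory]) -> None:
    """CSV log: fold, epoch, train_acc, train_loss, val_acc, val_loss."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["fold", "epoch", "train_acc", "train_loss", "val_acc", "val_loss"])
        for f, hist in enumerate(histories, start=1):
            for e in range(hist.stopped_epoch):
                w.writerow(
                    [f, e + 1, hist.train_acc[e], hist.train_loss[e],
                     hist.val_acc[e], hist.val_loss[e]]
                )
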