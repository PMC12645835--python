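"""Supervised training: loss, augmentation, optimizer loop, prediction.

Training minimizes the multi-class cross entropy with Adam, tracks
validation loss every epoch, restores the best-validation weights and
stops early after a patience window without improvement.  Every source of
randomness (weight init, shuffling, augmentation, dropout) derives from
the single seed in :class:`TrainParams`, so single-threaded runs are
exactly reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad
from autograd.tracer import getval

from ._nn import log_softmax, softmax, tree_map
from .architecture import DemuxTransModel, ModelConfig, model_forward
from .signal_io import SignalBatch, SignalSet, make_batches

__all__ = [
    "AugParams",
    "TrainParams",
    "TrainHistory",
    "cross_entropy",
    "augment",
    "train",
    "predict",
    "write_predictions",
    "read_predictions",
]


@dataclass(frozen=True)
class AugParams:
    """Stochastic training-time transforms of a signal batch.

    Per read, with probability ``apply_prob``: add Gaussian noise of s.d.
    ``noise_sd``, multiply by an amplitude factor uniform in
    ``scale_range``, and circularly shift by an integer uniform in
    ``[-shift_max, shift_max]``.  Labels are never touched.
    """

    noise_sd: float = 0.05
    scale_range: tuple[float, float] = (0.9, 1.1)
    shift_max: int = 16
    apply_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.scale_range
        if not (0 < lo <= 1 <= hi):
            raise ValueError("scale_range must satisfy 0 < lo <= 1 <= hi")
        if self.shift_max < 0:
            raise ValueError("shift_max must be >= 0")
        if not 0 <= self.apply_prob <= 1:
            raise ValueError("apply_prob must be in [0, 1]")


@dataclass(frozen=True)
class TrainParams:
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    early_stop_patience: int = 5
    seed: int = 0
    augmentation: AugParams = field(default_factory=AugParams)
    normalize_method: str = "median_mad"
    length_policy: str = "truncate_head"

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1 or self.early_stop_patience < 1:
            raise ValueError("batch_size and early_stop_patience must be >= 1")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("learning_rate must be > 0, weight_decay >= 0")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def n_epochs(self) -> int:
        return len(self.train_loss)


def cross_entropy(logits, labels) -> float:
    """Mean negative log-likelihood of the true labels under softmax.

    Differentiable through autograd when ``logits`` is traced.
    """
    labels = np.asarray(labels)
    n, C = getval(logits).shape
    if labels.shape != (n,):
        raise ValueError(f"labels must have shape ({n},)")
    if labels.min() < 0 or labels.max() >= C:
        raise ValueError(f"labels must lie in [0, {C})")
    onehot = np.eye(C)[labels]
    return -anp.mean(anp.sum(log_softmax(logits) * onehot, axis=1))


def augment(batch: SignalBatch, params: AugParams, seed: int) -> SignalBatch:
    """Apply the noise / amplitude-scale / circular-shift trio per read.

    Deterministic given ``seed``; labels and read order are unchanged.
    """
    rng = np.random.RandomState(seed)
    values = batch.values.copy()
    n, _, L = values.shape
    for i in range(n):
        if rng.rand() >= params.apply_prob:
            continue
        x = values[i, 0]
        if params.noise_sd > 0:
            x = x + rng.normal(0.0, params.noise_sd, size=L)
        lo, hi = params.scale_range
        if hi > lo:
            x = x * rng.uniform(lo, hi)
        elif lo != 1.0:
            x = x * lo
        if params.shift_max > 0:
            x = np.roll(x, rng.randint(-params.shift_max, params.shift_max + 1))
        values[i, 0] = x
    return SignalBatch(values=values, labels=batch.labels,
                       lengths=batch.lengths, read_ids=batch.read_ids)


# ---------------------------------------------------------------------------
# Adam
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, params, lr, weight_decay, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.wd, self.b1, self.b2, self.eps = lr, weight_decay, b1, b2, eps
        self.m = tree_map(lambda a: np.zeros_like(np.asarray(a, dtype=float)), params)
        self.v = tree_map(lambda a: np.zeros_like(np.asarray(a, dtype=float)), params)
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t

        def upd(p, g, m, v):
            g = g + self.wd * p          # decoupled-style L2 folded into the gradient
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            return p - self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

        return tree_map(upd, params, grads, self.m, self.v)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def _eval_loss_acc(model: DemuxTransModel, batches) -> tuple[float, float]:
    losses, correct, total = [], 0, 0
    for batch in batches:
        logits = model.forward(batch, mode="eval")
        losses.append(float(cross_entropy(logits, batch.labels)) * len(batch))
        preds = np.argmax(logits, axis=1)
        correct += int(np.sum(preds == batch.labels))
        total += len(batch)
    return sum(losses) / total, correct / total


def train(
    model_config: ModelConfig,
    train_set: SignalSet,
    val_set: SignalSet,
    params: TrainParams,
    log_path=None,
) -> tuple[DemuxTransModel, TrainHistory]:
    """Train the network on ``train_set``, early-stopping on ``val_set``.

    Returns the model restored to its best-validation-loss epoch together
    with the per-epoch history.  With ``epochs=0`` the freshly initialized
    model and an empty history are returned.  ``log_path``, when given,
    receives one JSON line of metrics per epoch.
    """
    if train_set.n_classes != model_config.n_classes or val_set.n_classes != model_config.n_classes:
        raise ValueError(
            f"class-count mismatch: model expects {model_config.n_classes}, "
            f"datasets have {train_set.n_classes}/{val_set.n_classes}"
        )
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    if train_set.labels is None or val_set.labels is None:
        raise ValueError("training requires fully labeled datasets")

    master = np.random.RandomState(params.seed)
    init_seed = master.randint(2 ** 31 - 1)
    model = DemuxTransModel(model_config, seed=init_seed)
    history = TrainHistory()
    if params.epochs == 0:
        return model, history

    L = model_config.input_length
    val_batches = make_batches(
        val_set, L, params.batch_size,
        normalize_method=params.normalize_method, length_policy=params.length_policy,
    )
    optimizer = _Adam(model.params, params.learning_rate, params.weight_decay)

    best = model.copy()
    best_loss = np.inf
    since_best = 0
    log_fh = open(log_path, "w") if log_path is not None else None

    try:
        for epoch in range(params.epochs):
            epoch_seed = master.randint(2 ** 31 - 1)
            erng = np.random.RandomState(epoch_seed)
            batches = make_batches(
                train_set, L, params.batch_size,
                normalize_method=params.normalize_method,
                length_policy=params.length_policy,
                shuffle=True, seed=erng.randint(2 ** 31 - 1),
            )
            epoch_loss, n_seen = 0.0, 0
            for batch in batches:
                batch = augment(batch, params.augmentation, erng.randint(2 ** 31 - 1))
                drop_rng = np.random.RandomState(erng.randint(2 ** 31 - 1))

                def loss_fn(p):
                    logits = model_forward(
                        batch, model_config, p, model.state,
                        mode="train", rng=drop_rng,
                    )
                    return cross_entropy(logits, batch.labels)

                loss, grads = value_and_grad(loss_fn)(model.params)
                model.params = optimizer.step(model.params, grads)
                epoch_loss += float(loss) * len(batch)
                n_seen += len(batch)

            train_loss = epoch_loss / n_seen
            val_loss, val_acc = _eval_loss_acc(model, val_batches)
            history.train_loss.append(train_loss)
            history.val_loss.append(val_loss)
            history.val_accuracy.append(val_acc)
            if log_fh is not None:
                log_fh.write(json.dumps({
                    "epoch": epoch, "train_loss": train_loss,
                    "val_loss": val_loss, "val_accuracy": val_acc,
                }) + "\n")
                log_fh.flush()

            if val_loss < best_loss:
                best_loss = val_loss
                best = model.copy()
                history.best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
                if since_best >= params.early_stop_patience:
                    break
    finally:
        if log_fh is not None:
            log_fh.close()
    return best, history


def predict(
    model: DemuxTransModel,
    sset: SignalSet,
    batch_size: int = 32,
    normalize_method: str = "median_mad",
    length_policy: str = "truncate_head",
) -> tuple[np.ndarray, np.ndarray]:
    """Eval-mode class probabilities and argmax labels for a dataset.

    Rows of the probability matrix sum to 1; ties in the logits resolve to
    the lowest class index (numpy argmax convention, documented contract).
    """
    batches = make_batches(
        sset, model.config.input_length, batch_size,
        normalize_method=normalize_method, length_policy=length_policy,
    )
    probs = []
    for batch in batches:
        logits = model.forward(batch, mode="eval")
        probs.append(softmax(np.asarray(logits), axis=1))
    prob = np.concatenate(probs, axis=0) if probs else np.zeros((0, model.config.n_classes))
    return prob, np.argmax(prob, axis=1)


def write_predictions(path, read_ids, preds, probs) -> None:
    """Write a predictions TSV: read_id, predicted label, per-class probs."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("read_id\tpred_label\tprobs\n")
        for rid, pred, row in zip(read_ids, preds, probs):
            fh.write(f"{rid}\t{int(pred)}\t{','.join(repr(float(p)) for p in row)}\n")


def read_predictions(path) -> tuple[list[str], np.ndarray, np.ndarray]:
    ids, preds, probs = [], [], []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != "read_id\tpred_label\tprobs":
            raise ValueError(f"{path}: unexpected predictions header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields")
            ids.append(parts[0])
            preds.append(int(parts[1]))
            probs.append([float(tok) for tok in parts[2].split(",")])
    return ids, np.asarray(preds, dtype=np.int64), np.asarray(probs)
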