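"""Mini-batch Adam training with early stopping on validation accuracy.

The regime: NLL loss on log-softmax outputs, Adam (lr 1e-3, batch 64),
at most 200 epochs, halting when validation binary accuracy has not
strictly improved for `patience` (default 20) consecutive epochs; the
parameters from the best epoch are restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from numpy.random import default_rng

from .model import ModelParams, backward, forward, predict_log_probs


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 20
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    shuffle_seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


@dataclass
class History:
    train_loss: List[float] = field(default_factory=list)
    val_accuracy: List[float] = field(default_factory=list)
    best_epoch: int = 0
    stop_epoch: int = 0


class _Adam:
    def __init__(self, cfg: TrainConfig, arrays: Dict[str, np.ndarray]):
        self.cfg = cfg
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in arrays.items()}
        self.v = {k: np.zeros_like(v) for k, v in arrays.items()}

    def step(self, arrays: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        c = self.cfg
        self.t += 1
        b1t = 1 - c.beta1 ** self.t
        b2t = 1 - c.beta2 ** self.t
        for k, g in grads.items():
            m, v = self.m[k], self.v[k]
            m *= c.beta1
            m += (1 - c.beta1) * g
            v *= c.beta2
            v += (1 - c.beta2) * g * g
            arrays[k] -= c.learning_rate * (m / b1t) / (np.sqrt(v / b2t) + c.adam_eps)


def _nll(log_probs: np.ndarray, labels: np.ndarray) -> float:
    return float(-log_probs[np.arange(len(labels)), labels].mean())


def binary_accuracy(params: ModelParams, X: np.ndarray, y: np.ndarray) -> float:
    """Evaluation-mode argmax accuracy."""
    preds = predict_log_probs(params, X).argmax(axis=1)
    return float((preds == y).mean())


def train_model(params: ModelParams, train_X: np.ndarray, train_y: np.ndarray,
                val_X: np.ndarray, val_y: np.ndarray, cfg: TrainConfig,
                seed: Optional[int] = None) -> Tuple[ModelParams, History]:
    """Optimize ``params`` in place on trial-level epochs; return best weights.

    ``seed`` overrides ``cfg.shuffle_seed`` for batch shuffling.  Raises on a
    single-class training or validation split, and aborts with a diagnostic
    if the loss turns non-finite.
    """
    train_y = np.asarray(train_y, dtype=int)
    val_y = np.asarray(val_y, dtype=int)
    if len(train_X) == 0 or len(val_X) == 0:
        raise ValueError("training and validation splits must be non-empty")
    if len(np.unique(train_y)) < 2:
        raise ValueError("training split contains a single class")
    if len(np.unique(val_y)) < 2:
        raise ValueError("validation split contains a single class")

    rng = default_rng(cfg.shuffle_seed if seed is None else seed)
    opt = _Adam(cfg, params.trainable())
    hist = History()
    best_acc = -np.inf
    best_params = params.copy()
    since_best = 0
    n = len(train_X)

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            log_p, acts, cache = forward(params, train_X[idx], train_mode=True,
                                         return_cache=True)
            loss = _nll(log_p, train_y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(batch starting {start}); try a smaller learning rate")
            losses.append(loss)
            grads = backward(params, acts, cache, train_y[idx])
            opt.step(params.trainable(), grads)
        hist.train_loss.append(float(np.mean(losses)))

        acc = binary_accuracy(params, val_X, val_y)
        hist.val_accuracy.append(acc)
        if acc > best_acc:  # strict improvement; ties do not reset patience
            best_acc = acc
            hist.best_epoch = epoch
            best_params = params.copy()
            since_best = 0
        else:
            since_best += 1
        hist.stop_epoch = epoch
        if since_best >= max(cfg.patience, 1):
            break

    return best_params, hist
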