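"""Fine-tuning and evaluation of prunable encoders.

Two regimes mirror how pretrained genomic language models are fine-tuned
in practice on the variant classification task:

* ``to_convergence`` — train until the validation loss stops improving
  (absolute improvement tolerance + patience), restoring the weights of
  the best validation epoch;
* ``fixed_epochs`` — train for exactly ``fixed_epochs`` epochs (the
  budget-constrained regime used when convergence training is too
  expensive) and keep the final weights.

The optimizer is Adam. The fine-tuning seed controls everything downstream
of the pretrained weights: classification-head re-initialization and the
per-epoch shuffling of the training data. The pretrained weights are never
re-drawn.
"""

from __future__ import annotations

import csv
import json
import math
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .datasets import DatasetSplit
from .encoder import TinyEncoder, iter_params
from .errors import (
    InvalidArgumentError,
    InvalidDataError,
    NumericFailureError,
)
from .metrics import EvalResult, compute_metrics


@dataclass(frozen=True)
class FineTuneConfig:
    """Hyperparameters of one fine-tune + evaluate run.

    ``threshold`` is the decision threshold on the positive-class score
    at evaluation time. ``reinit_head`` draws a fresh classification head
    from ``seed`` before training, the usual protocol when attaching a
    task head to a pretrained encoder. ``class_weights`` is a config hook
    for loss re-weighting; it is accepted and recorded but the default
    loss is unweighted.
    """

    mode: str = "to_convergence"
    max_epochs: int = 50
    patience: int = 5
    fixed_epochs: int = 5
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0
    threshold: float = 0.5
    deterministic: bool = True
    convergence_tol: float = 1e-4
    reinit_head: bool = True
    class_weights: tuple[float, float] | None = None

    def __post_init__(self):
        if self.mode not in ("to_convergence", "fixed_epochs"):
            raise InvalidArgumentError("mode must be to_convergence or fixed_epochs")
        if self.patience < 1 or self.fixed_epochs < 1 or self.max_epochs < 1:
            raise InvalidArgumentError("patience, fixed_epochs, max_epochs must be >= 1")
        if not 0.0 < self.threshold < 1.0:
            raise InvalidArgumentError("threshold must lie in (0, 1)")
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise InvalidArgumentError("learning_rate > 0 and batch_size >= 1 required")


@dataclass
class EpochEntry:
    epoch: int
    train_loss: float
    val_loss: float


@dataclass
class TrainingLog:
    entries: list[EpochEntry] = field(default_factory=list)
    stop_reason: str = ""
    wall_seconds: float = 0.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "stop_reason": self.stop_reason,
                "wall_seconds": self.wall_seconds,
                "entries": [asdict(e) for e in self.entries],
            },
            indent=2,
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "train_loss", "val_loss"])
            for e in self.entries:
                w.writerow([e.epoch, repr(e.train_loss), repr(e.val_loss)])
        return path


class _Adam:
    """Standard Adam over a parameter tree addressed by path."""

    def __init__(self, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        grad_by_path = dict(iter_params(grads))
        for path, arr in iter_params(params):
            g = grad_by_path[path]
            m = self.m.setdefault(path, np.zeros_like(arr))
            v = self.v.setdefault(path, np.zeros_like(arr))
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            arr -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _mean_loss(model: TinyEncoder, tokens: np.ndarray, labels: np.ndarray,
               batch_size: int = 256) -> float:
    """Full-split mean cross-entropy without gradient computation."""
    total, n = 0.0, tokens.shape[0]
    eps = 1e-12
    for i in range(0, n, batch_size):
        tb, lb = tokens[i : i + batch_size], labels[i : i + batch_size]
        logits = model.forward_logits(tb)
        z = logits - logits.max(axis=1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        total += float(-logp[np.arange(len(lb)), lb].sum())
    return total / n


def fine_tune(
    model: TinyEncoder,
    train: DatasetSplit,
    val: DatasetSplit,
    cfg: FineTuneConfig,
) -> tuple[TinyEncoder, TrainingLog]:
    """Fine-tune a copy of ``model``; the input model is left untouched.

    Returns the trained model and its :class:`TrainingLog`. In
    ``to_convergence`` mode the best-validation-loss weights are restored
    before returning.
    """
    if len(train) == 0 or len(val) == 0:
        raise InvalidDataError("train and validation splits must be non-empty")
    train_labels = train.labels
    if train_labels.min() == train_labels.max():
        raise InvalidDataError("training split contains a single class")

    t0 = time.perf_counter()
    m = model.clone()
    if cfg.reinit_head:
        m.reinit_head(cfg.seed)

    tokens = m.tokenize(train.sequences)
    val_tokens = m.tokenize(val.sequences)
    val_labels = val.labels

    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x7A1]))
    opt = _Adam(cfg.learning_rate)
    log = TrainingLog()

    n = tokens.shape[0]
    n_epochs = cfg.fixed_epochs if cfg.mode == "fixed_epochs" else cfg.max_epochs
    best_val = math.inf
    best_params = None
    stall = 0
    stop_reason = "fixed_epochs" if cfg.mode == "fixed_epochs" else "max_epochs"

    for epoch in range(1, n_epochs + 1):
        order = rng.permutation(n)
        running, seen = 0.0, 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            loss, grads = m.loss_and_grads(tokens[idx], train_labels[idx])
            if not math.isfinite(loss):
                raise NumericFailureError(f"non-finite training loss at epoch {epoch}")
            opt.step(m.params, grads)
            running += loss * len(idx)
            seen += len(idx)
        train_loss = running / seen
        val_loss = _mean_loss(m, val_tokens, val_labels)
        if not math.isfinite(val_loss):
            raise NumericFailureError(f"non-finite validation loss at epoch {epoch}")
        log.entries.append(EpochEntry(epoch, train_loss, val_loss))

        if cfg.mode == "to_convergence":
            if val_loss < best_val - cfg.convergence_tol:
                best_val = val_loss
                best_params = {p: a.copy() for p, a in iter_params(m.params)}
                stall = 0
            else:
                stall += 1
                if stall >= cfg.patience:
                    stop_reason = "converged"
                    break

    if cfg.mode == "to_convergence" and best_params is not None:
        for path, arr in iter_params(m.params):
            arr[...] = best_params[path]
    log.stop_reason = stop_reason
    log.wall_seconds = time.perf_counter() - t0
    return m, log


def predict_scores(model: TinyEncoder, split: DatasetSplit) -> np.ndarray:
    """Positive-class score in [0, 1] for every record, order-aligned."""
    if len(split) == 0:
        raise InvalidDataError("cannot score an empty split")
    return model.predict_proba(split.sequences)[:, 1]


def evaluate(
    model: TinyEncoder, test: DatasetSplit, threshold: float = 0.5, seed: int = 0
) -> EvalResult:
    """Score a split and compute the full metric set, recording wall time."""
    t0 = time.perf_counter()
    scores = predict_scores(model, test)
    result = compute_metrics(test.labels, scores, threshold)
    result.eval_seconds = time.perf_counter() - t0
    result.seed = int(seed)
    return result
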