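"""Training loop: Adam on the CTC loss over labeled signal windows.

The loop follows the original recipe at configurable scale: Adam with an
initial learning rate of 0.004, mini-batches of windows, the training set
reshuffled every epoch, the validation loss computed every ``validate_every``
iterations, a stepped learning-rate decay, and the best-validation weights
retained as the returned checkpoint.  Everything is a pure function of the
seed, so two runs with identical configs produce identical metric logs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .ctc import ctc_loss_and_grad
from .model import TCNModel
from .nn import Param
from .simulate import read_training_archive

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TrainResult", "Adam", "train_model", "write_metrics_tsv"]


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    ``batch_size`` 256 and ``learning_rate`` 0.004 are the full-scale
    defaults; desk-scale runs typically use batch 16.  The learning rate at
    iteration i is ``learning_rate * lr_step_factor ** floor(i / lr_step_every)``.
    """

    batch_size: int = 256
    learning_rate: float = 0.004
    lr_step_factor: float = 0.5
    lr_step_every: int = 2000
    warmup_iterations: int = 0
    validate_every: int = 10
    max_iterations: int = 1000
    seed: int = 0
    shuffle_each_epoch: bool = True
    val_subset_size: int = 32

    def __post_init__(self) -> None:
        if min(self.batch_size, self.lr_step_every, self.validate_every) < 1:
            raise ValueError("batch_size, lr_step_every, validate_every must be >= 1")
        if self.learning_rate <= 0 or not 0 < self.lr_step_factor <= 1:
            raise ValueError("learning_rate > 0 and 0 < lr_step_factor <= 1 required")
        if self.max_iterations < 0 or self.warmup_iterations < 0:
            raise ValueError("max_iterations and warmup_iterations must be >= 0")

    def lr_at(self, iteration: int) -> float:
        lr = self.learning_rate * self.lr_step_factor ** (iteration // self.lr_step_every)
        if self.warmup_iterations and iteration < self.warmup_iterations:
            lr *= (iteration + 1) / self.warmup_iterations
        return lr


@dataclass
class TrainResult:
    model: TCNModel
    log: list[dict]
    best_val_loss: float
    best_iteration: int


class Adam:
    """Adam optimizer over a list of Params."""

    def __init__(
        self,
        params: Sequence[Param],
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)


def _load_data(
    data: str | Path | tuple,
) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    if isinstance(data, (str, Path)):
        return read_training_archive(data)
    signals, labels = data[0], data[1]
    valid = data[2] if len(data) > 2 else np.full(len(signals), signals.shape[1])
    return np.asarray(signals), [np.asarray(y) for y in labels], np.asarray(valid)


def _filter_feasible(
    signals: np.ndarray, labels: list[np.ndarray], valid: np.ndarray, what: str
) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """Drop examples whose label cannot have positive probability: a CTC path
    needs one frame per base plus one blank between each adjacent repeat."""
    def min_frames(y: np.ndarray) -> int:
        return len(y) + int(np.sum(y[1:] == y[:-1])) if len(y) else 0

    keep = np.array([min_frames(y) <= v for y, v in zip(labels, valid)])
    if not keep.all():
        logger.warning(
            "%s: skipping %d/%d examples whose labels are too long for their "
            "valid frame count", what, int((~keep).sum()), len(keep),
        )
    return (
        signals[keep],
        [y for y, k in zip(labels, keep) if k],
        valid[keep],
    )


def _eval_loss(
    model: TCNModel, signals: np.ndarray, labels: list[np.ndarray],
    valid: np.ndarray, batch_size: int,
) -> float:
    total, n = 0.0, 0
    for i in range(0, len(signals), batch_size):
        lp = model.forward_log_probs(signals[i : i + batch_size])
        losses, _ = ctc_loss_and_grad(lp, labels[i : i + batch_size], valid[i : i + batch_size])
        finite = np.isfinite(losses)
        total += float(losses[finite].sum())
        n += int(finite.sum())
    return total / max(n, 1)


def train_model(
    model: TCNModel,
    train_data: str | Path | tuple,
    val_data: str | Path | tuple | None,
    config: TrainConfig,
    metrics_path: str | Path | None = None,
) -> TrainResult:
    """Train in place; return the model restored to its best-validation weights.

    ``train_data``/``val_data`` are either archive paths or
    ``(signals, labels[, valid_lengths])`` tuples.  The validation loss is
    computed on a fixed random subset of ``val_subset_size`` examples
    (evaluating the full set every few iterations would dominate the run).
    """
    signals, labels, valid = _filter_feasible(*_load_data(train_data), what="training set")
    if len(signals) == 0:
        raise ValueError("training set is empty after feasibility filtering")
    rng = np.random.default_rng(config.seed)

    have_val = val_data is not None
    if have_val:
        vs, vl, vv = _filter_feasible(*_load_data(val_data), what="validation set")
        if len(vs) == 0:
            raise ValueError("validation set is empty after feasibility filtering")
        sub = rng.permutation(len(vs))[: config.val_subset_size]
        vs, vl, vv = vs[sub], [vl[i] for i in sub], vv[sub]

    opt = Adam(model.params)
    log: list[dict] = []
    best_val = math.inf
    best_iter = -1
    best_state = model.get_state()

    iteration = 0
    order = np.arange(len(signals))
    while iteration < config.max_iterations:
        if config.shuffle_each_epoch or iteration == 0:
            order = rng.permutation(len(signals))
        for start in range(0, len(order), config.batch_size):
            if iteration >= config.max_iterations:
                break
            idx = order[start : start + config.batch_size]
            lp = model.forward_log_probs(signals[idx])
            losses, grad = ctc_loss_and_grad(lp, [labels[i] for i in idx], valid[idx])
            finite = np.isfinite(losses)
            train_loss = float(losses[finite].mean()) if finite.any() else math.nan
            # mean over batch; grad is w.r.t. logits (B, T, 5) -> (B, 5, T)
            model.zero_grad()
            model.backward(np.transpose(grad, (0, 2, 1)) / max(int(finite.sum()), 1))
            lr = config.lr_at(iteration)
            opt.step(lr)

            row = {"iteration": iteration, "train_loss": train_loss, "lr": lr,
                   "val_loss": math.nan}
            if have_val and (iteration % config.validate_every == 0
                             or iteration == config.max_iterations - 1):
                vloss = _eval_loss(model, vs, vl, vv, config.batch_size)
                row["val_loss"] = vloss
                if vloss < best_val:
                    best_val = vloss
                    best_iter = iteration
                    best_state = model.get_state()
            log.append(row)
            iteration += 1

    if have_val and best_iter >= 0:
        model.set_state(best_state)
    if metrics_path is not None:
        write_metrics_tsv(log, metrics_path)
    return TrainResult(model=model, log=log, best_val_loss=best_val, best_iteration=best_iter)


def write_metrics_tsv(log: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("iteration\ttrain_loss\tval_loss\tlr\n")
        for row in log:
            val = "" if math.isnan(row["val_loss"]) else f"{row['val_loss']:.6f}"
            tl = "" if math.isnan(row["train_loss"]) else f"{row['train_loss']:.6f}"
            fh.write(f"{row['iteration']}\t{tl}\t{val}\t{row['lr']:.6g}\n")
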