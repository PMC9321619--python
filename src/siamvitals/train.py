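"""Negative-Pearson-correlation loss and the Adam training loop.

The model is trained to reproduce the *shape* of the reference traces, not
their scale: the loss for each task is ``1 - r(x, y)`` where ``r`` is the
Pearson correlation between the reference and predicted trace, so every
per-task loss lies in [0, 2] and is invariant to positive affine rescaling
of the prediction. The multitask loss is a nonnegative weighted sum of the
PPG and respiration losses (unweighted by default).

Training follows the published recipe: Adam with learning rate 1e-4,
beta1 = 0.9, beta2 = 0.999, batch size one (one clip per step), and an
upper bound of 250 epochs; the checkpoint with the lowest validation total
loss is retained. Loss is computed per clip over all T samples. Everything
is reproducible given the seed.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import SiameseVitalsNet
from .nn import Adam

__all__ = [
    "TrainConfig",
    "LossValue",
    "pearson_r",
    "pearson_loss",
    "pearson_loss_grad",
    "multitask_loss",
    "split_dataset",
    "fit",
]

#: A dataset item: ((forehead, cheek), (ppg_truth, resp_truth_or_None))
Item = tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray | None]]


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and loop hyperparameters (defaults: the published recipe)."""

    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    max_epochs: int = 250
    batch_size: int = 1
    loss_weights: tuple[float, float] = (1.0, 1.0)
    split_ratio: tuple[float, float, float] = (3.0, 1.0, 1.0)
    early_stop_patience: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if any(w < 0 for w in self.loss_weights) or sum(self.loss_weights) == 0:
            raise ValueError("loss weights must be nonnegative, not both zero")
        if any(r <= 0 for r in self.split_ratio):
            raise ValueError("split ratios must be positive")
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("max_epochs and batch_size must be >= 1")


@dataclass
class LossValue:
    """Total loss and its per-task decomposition."""

    total: float
    per_task: dict[str, float]
    degenerate: bool = False


def pearson_r(
    x: np.ndarray, y: np.ndarray, *, return_degenerate: bool = False
) -> float | tuple[float, bool]:
    """Pearson correlation of two vectors, in [-1, 1].

    A constant input makes the correlation undefined; the fallback returns
    0 (so the corresponding loss is 1) and, with ``return_degenerate=True``,
    flags the case instead of dividing by zero. This keeps training alive on
    pathological batches.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"vectors must be 1-D and equal length, got {x.shape}, {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = math.sqrt(float(dx @ dx))
    sy = math.sqrt(float(dy @ dy))
    if sx == 0.0 or sy == 0.0:
        return (0.0, True) if return_degenerate else 0.0
    r = float(dx @ dy) / (sx * sy)
    r = min(1.0, max(-1.0, r))
    return (r, False) if return_degenerate else r


def pearson_loss(x: np.ndarray, y: np.ndarray) -> float:
    """1 - r(x, y); zero for perfectly correlated traces, 2 for anticorrelated."""
    return 1.0 - pearson_r(x, y)


def pearson_loss_grad(truth: np.ndarray, pred: np.ndarray) -> tuple[float, np.ndarray]:
    """Loss 1 - r(truth, pred) and its gradient with respect to ``pred``.

    With centered vectors x = truth - mean, y = pred - mean and norms
    sx, sy: dr/dpred = x / (sx sy) - r y / sy^2, which already sums to zero,
    so no extra centering projection is needed. Degenerate (constant) input
    yields loss 1 and a zero gradient.
    """
    truth = np.asarray(truth, dtype=float)
    pred = np.asarray(pred, dtype=float)
    dx = truth - truth.mean()
    dy = pred - pred.mean()
    sx = math.sqrt(float(dx @ dx))
    sy = math.sqrt(float(dy @ dy))
    if sx == 0.0 or sy == 0.0:
        return 1.0, np.zeros_like(pred)
    r = float(dx @ dy) / (sx * sy)
    grad = -(dx / (sx * sy) - r * dy / sy**2)
    return 1.0 - r, grad


def multitask_loss(
    pred_ppg: np.ndarray,
    pred_resp: np.ndarray | None,
    truth_ppg: np.ndarray,
    truth_resp: np.ndarray | None,
    weights: tuple[float, float] = (1.0, 1.0),
) -> LossValue:
    """Weighted sum of per-task Pearson losses; each per-task loss in [0, 2]."""
    w_ppg, w_resp = weights
    r_ppg, deg_ppg = pearson_r(truth_ppg, pred_ppg, return_degenerate=True)
    per_task = {"ppg": 1.0 - r_ppg}
    degenerate = deg_ppg
    total = w_ppg * per_task["ppg"]
    if pred_resp is not None and truth_resp is not None:
        if len(pred_resp) != len(truth_resp):
            raise ValueError("respiration prediction/truth length mismatch")
        r_resp, deg_resp = pearson_r(truth_resp, pred_resp, return_degenerate=True)
        per_task["respiration"] = 1.0 - r_resp
        total += w_resp * per_task["respiration"]
        degenerate = degenerate or deg_resp
    return LossValue(total=float(total), per_task=per_task, degenerate=degenerate)


def split_dataset(
    items: Sequence, ratio: tuple[float, float, float], seed: int
) -> tuple[list, list, list]:
    """Split items train:val:test by a seeded shuffle; remainders go to train."""
    n = len(items)
    total = sum(ratio)
    n_val = int(n * ratio[1] / total)
    n_test = int(n * ratio[2] / total)
    order = np.random.default_rng(seed).permutation(n)
    val_idx = order[:n_val]
    test_idx = order[n_val : n_val + n_test]
    train_idx = order[n_val + n_test :]
    pick = lambda idx: [items[i] for i in idx]  # noqa: E731
    return pick(train_idx), pick(val_idx), pick(test_idx)


def _evaluate(net: SiameseVitalsNet, items: Sequence[Item],
              weights: tuple[float, float]) -> dict[str, float]:
    totals: dict[str, list[float]] = {"total": [], "ppg": [], "respiration": []}
    for (forehead, cheek), (ppg_t, resp_t) in items:
        pred = net.forward(forehead, cheek, training=False)
        net._cache = None
        lv = multitask_loss(pred.ppg, pred.respiration, ppg_t,
                            resp_t if pred.respiration is not None else None, weights)
        totals["total"].append(lv.total)
        totals["ppg"].append(lv.per_task["ppg"])
        if "respiration" in lv.per_task:
            totals["respiration"].append(lv.per_task["respiration"])
    out = {k: float(np.mean(v)) for k, v in totals.items() if v}
    return out


def fit(
    net: SiameseVitalsNet,
    train_items: Sequence[Item],
    config: TrainConfig,
    val_items: Sequence[Item] | None = None,
    *,
    checkpoint_path: str | Path | None = None,
    restore_best: bool = True,
    verbose: bool = False,
) -> pd.DataFrame:
    """Train with Adam, batch size one; retain the best-validation weights.

    Items are ``((forehead, cheek), (ppg_truth, resp_truth))`` with each ROI
    tensor shaped (T, h, w, 3). Per epoch the training items are visited in
    a seeded shuffled order; validation (or, lacking one, training) loss
    selects the retained checkpoint. A non-finite loss aborts with the
    offending epoch. Returns the per-epoch history.
    """
    if len(train_items) == 0:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    params = net.parameters()
    opt = Adam(params, lr=config.learning_rate,
               beta1=config.beta1, beta2=config.beta2)
    weights = config.loss_weights

    history: list[dict] = []
    best = (np.inf, None, -1)  # (monitored loss, state, epoch)
    stale = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_items))
        epoch_losses: dict[str, list[float]] = {"total": [], "ppg": [], "respiration": []}
        for i in order:
            (forehead, cheek), (ppg_t, resp_t) = train_items[i]
            pred = net.forward(forehead, cheek, training=True, rng=rng)
            use_resp = pred.respiration is not None and resp_t is not None
            loss_ppg, grad_ppg = pearson_loss_grad(ppg_t, pred.ppg)
            total = weights[0] * loss_ppg
            grad_resp = None
            if use_resp:
                loss_resp, grad_resp = pearson_loss_grad(resp_t, pred.respiration)
                total += weights[1] * loss_resp
                grad_resp = weights[1] * grad_resp
                epoch_losses["respiration"].append(loss_resp)
            if not np.isfinite(total):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            net.backward(weights[0] * grad_ppg, grad_resp)
            opt.step()
            epoch_losses["total"].append(total)
            epoch_losses["ppg"].append(loss_ppg)

        row = {"epoch": epoch}
        row.update({f"train_{k}": float(np.mean(v))
                    for k, v in epoch_losses.items() if v})
        if val_items:
            val = _evaluate(net, val_items, weights)
            row.update({f"val_{k}": v for k, v in val.items()})
            monitored = val["total"]
        else:
            monitored = row["train_total"]
        history.append(row)
        if verbose:  # pragma: no cover
            print(f"epoch {epoch}: " + ", ".join(
                f"{k}={v:.4f}" for k, v in row.items() if k != "epoch"))
        if monitored < best[0]:
            best = (monitored, copy.deepcopy(net.state_dict()), epoch)
            stale = 0
        else:
            stale += 1
            if (config.early_stop_patience is not None
                    and stale > config.early_stop_patience):
                break

    if restore_best and best[1] is not None:
        net.load_state_dict(best[1])
    if checkpoint_path is not None:
        net.save(checkpoint_path)
    df = pd.DataFrame(history)
    df.attrs["best_epoch"] = best[2]
    return df
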