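"""Training loop: Adam on voxelwise binary cross-entropy.

The recipe mirrors common practice for sigmoid occupancy grids:
learning rate 1e-4, an effective batch size of 16 reached through
gradient accumulation, and early stopping on the validation loss.
Scale (grid resolution, crop size, dataset size) comes from the model
and dataset configurations, so the same loop runs the full-size recipe
and the CPU desk preset.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .dataset import ReconSample
from .geometry import ProjectionMatrix
from .metrics import MetricsReport, compare_grids
from .network import ReconstructionNet

__all__ = [
    "TrainConfig",
    "Adam",
    "train_model",
    "evaluate_model",
    "aggregate_reports",
    "early_stop_epoch",
    "sample_loss",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    effective_batch_size: int = 16
    accumulation_steps: int = 16
    max_epochs: int = 40
    patience: int = 5
    n_views: int = 4
    variant: str = "unsegmented"
    pos_weight: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.effective_batch_size % self.accumulation_steps:
            raise ValueError(
                "effective_batch_size must be a multiple of accumulation_steps")
        if self.n_views not in (4, 8):
            raise ValueError("n_views must be 4 or 8")

    @property
    def per_step_batch(self) -> int:
        return self.effective_batch_size // self.accumulation_steps


class Adam:
    """Adaptive-moment optimizer over a list of autodiff tensors."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)

    def state(self) -> dict:
        return {"t": self.t, "m": self.m, "v": self.v}


def sample_loss(model: ReconstructionNet, sample: ReconSample,
                pos_weight: float = 1.0) -> ad.Tensor:
    """Voxelwise BCE between predicted logits and the occupancy target."""
    logits = model.forward(sample.images, sample.p_hats, sample.grid)
    return ad.bce_with_logits(logits, sample.gt.values.astype(np.float32),
                              pos_weight=pos_weight)


def early_stop_epoch(val_losses: list[float], patience: int) -> int | None:
    """Epoch index (1-based) at which training stops, or None.

    Stops after ``patience`` consecutive epochs without improving on the
    best validation loss seen so far.
    """
    best = np.inf
    since = 0
    for i, v in enumerate(val_losses, start=1):
        if v < best - 1e-12:
            best = v
            since = 0
        else:
            since += 1
            if since >= patience:
                return i
    return None


def _eval_loss(model: ReconstructionNet, samples: list[ReconSample],
               pos_weight: float = 1.0) -> float:
    return float(np.mean([sample_loss(model, s, pos_weight).item()
                          for s in samples]))


def train_model(
    model: ReconstructionNet,
    train_samples: list[ReconSample],
    val_samples: list[ReconSample],
    cfg: TrainConfig,
    log_path: str | Path | None = None,
    max_steps_per_epoch: int | None = None,
) -> dict:
    """Optimize the network; returns the training log.

    One step processes ``accumulation_steps`` samples, accumulating the
    gradient of each sample's mean BCE divided by the number of
    accumulation slots — numerically equal to a single large batch.
    Stops on validation-loss patience or ``max_epochs``.
    """
    if not train_samples or not val_samples:
        raise ValueError("need non-empty train and validation sample lists")
    rng = np.random.default_rng(cfg.rng_seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    log: dict = {"epoch": [], "train_loss": [], "val_loss": []}
    k = cfg.accumulation_steps
    stopped = None
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(train_samples))
        losses = []
        pending = 0
        model.zero_grad()
        for n, i in enumerate(order):
            if max_steps_per_epoch is not None and n >= max_steps_per_epoch * k:
                break
            loss = sample_loss(model, train_samples[i], cfg.pos_weight)
            if not np.isfinite(loss.item()):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            loss.backward(np.float32(1.0 / k))
            losses.append(loss.item())
            pending += 1
            if pending == k:
                opt.step()
                model.zero_grad()
                pending = 0
        if pending:
            opt.step()
            model.zero_grad()
        val = _eval_loss(model, val_samples, cfg.pos_weight)
        log["epoch"].append(epoch)
        log["train_loss"].append(float(np.mean(losses)))
        log["val_loss"].append(val)
        stopped = early_stop_epoch(log["val_loss"], cfg.patience)
        if stopped is not None:
            break
    log["stopped_epoch"] = stopped
    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "train_loss", "val_loss"])
            for row in zip(log["epoch"], log["train_loss"], log["val_loss"]):
                w.writerow(row)
    return log


def evaluate_model(
    model: ReconstructionNet,
    samples: list[ReconSample],
    d_fraction: float = 0.01,
    n_points: int = 2000,
    rng_seed: int = 0,
) -> tuple[list[MetricsReport], dict]:
    """Reconstruct every sample and score it; returns reports + aggregate."""
    reports = []
    levels = []
    for s in samples:
        _, binary = model.reconstruct(s.images, s.p_hats, s.grid)
        reports.append(compare_grids(binary, s.gt, d_fraction=d_fraction,
                                     n_points=n_points, rng_seed=rng_seed))
        levels.append(s.level)
    return reports, aggregate_reports(reports, levels)


def aggregate_reports(reports: list[MetricsReport], levels: list[int]) -> dict:
    """Mean +- std per metric, overall and per vertebral level."""
    keys = ["f1", "iou", "precision_d", "recall_d", "surface_score", "hd95", "asd"]

    def agg(rs):
        return {k: (float(np.mean([getattr(r, k) for r in rs])),
                    float(np.std([getattr(r, k) for r in rs]))) for k in keys}

    out = {"overall": agg(reports), "per_level": {}}
    for lev in sorted(set(levels)):
        rs = [r for r, l in zip(reports, levels) if l == lev]
        out["per_level"][lev] = agg(rs)
    return out
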