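"""Model training: soft Dice loss, Adam with exponential lr decay,
volume-level 5-fold cross-validation and early stopping on validation IoU.

The loss is the smoothed soft Dice

    L = 1 − (2·Σ(p·t) + s) / (Σp + Σt + s),   s = 1 by default,

summed over a whole batch, which is safe for empty targets (empty/empty
gives loss 0).  The learning rate follows a continuous exponential decay
``lr0 · rate^(step / decay_steps)`` with the reference constants lr0 = 1e-4,
253 decay steps and rate 0.96.  Folds are assigned at the volume level so
that a volume's slices never straddle the train/validation boundary, and the
assignment is fixed once and reused by every self-training round.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .augmentation import AugmentationPolicy, augment_dataset, stratify_by_area
from .metrics import iou
from .model import ResUnetConfig, ResUNet, binarize, build_model
from .nn import Adam

__all__ = [
    "TrainConfig", "FoldSplit", "dice_loss", "dice_loss_grad", "lr_at",
    "make_folds", "EarlyStopping", "train_fold", "train_round",
]


@dataclass
class TrainConfig:
    lr0: float = 0.0001
    decay_steps: int = 253
    decay_rate: float = 0.96
    max_epochs: int = 100
    patience: int = 10
    n_folds: int = 5
    dice_smooth: float = 1.0
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be > 0")
        if not 0 < self.decay_rate <= 1:
            raise ValueError("decay_rate must be in (0, 1]")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")


@dataclass
class FoldSplit:
    """pair-index → fold assignment, computed at volume level."""

    assignments: dict          # pair index -> fold
    volume_fold: dict          # volume id -> fold
    n_folds: int

    def train_indices(self, fold: int) -> list:
        return [i for i, f in self.assignments.items() if f != fold]

    def val_indices(self, fold: int) -> list:
        return [i for i, f in self.assignments.items() if f == fold]


def dice_loss(pred, target, smooth: float = 1.0) -> float:
    """Soft Dice loss of a probability map against a binary target."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    inter = float((pred * target).sum())
    denom = float(pred.sum() + target.sum())
    return 1.0 - (2.0 * inter + smooth) / (denom + smooth)


def dice_loss_grad(pred, target, smooth: float = 1.0) -> np.ndarray:
    """∂(dice_loss)/∂pred, used to seed backpropagation."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    inter = (pred * target).sum()
    denom = pred.sum() + target.sum() + smooth
    return -(2.0 * target * denom - (2.0 * inter + smooth)) / denom ** 2


def lr_at(step: int, cfg: TrainConfig) -> float:
    """Continuous exponential decay: lr0 · rate^(step / decay_steps)."""
    return cfg.lr0 * cfg.decay_rate ** (step / cfg.decay_steps)


def make_folds(pairs, n_folds: int, seed: int) -> FoldSplit:
    """Shuffle volumes with ``seed`` and deal them round-robin into folds."""
    vol_ids = []
    for p in pairs:
        if p.volume_id not in vol_ids:
            vol_ids.append(p.volume_id)
    if len(vol_ids) < n_folds:
        raise ValueError(f"need at least {n_folds} volumes, got {len(vol_ids)}")
    order = list(np.random.default_rng(seed).permutation(len(vol_ids)))
    volume_fold = {vol_ids[j]: i % n_folds for i, j in enumerate(order)}
    assignments = {i: volume_fold[p.volume_id] for i, p in enumerate(pairs)}
    return FoldSplit(assignments=assignments, volume_fold=volume_fold,
                     n_folds=n_folds)


class EarlyStopping:
    """Stop when the monitored metric has not improved for ``patience`` epochs."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = -np.inf
        self.best_epoch = -1
        self.stale = 0

    def update(self, metric: float, epoch: int) -> bool:
        """Record an epoch's metric; return True if training should stop."""
        if metric > self.best:
            self.best = metric
            self.best_epoch = epoch
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


def _batch_arrays(pairs, indices):
    x = np.stack([np.transpose(pairs[i].image.data, (2, 0, 1)) for i in indices])
    t = np.stack([pairs[i].mask.mask[None].astype(np.float64) for i in indices])
    return x.astype(np.float64), t


def _mean_val_iou(net: ResUNet, pairs, indices, threshold: float,
                  batch_size: int) -> float:
    scores = []
    for i in range(0, len(indices), batch_size):
        chunk = indices[i:i + batch_size]
        x, t = _batch_arrays(pairs, chunk)
        prob = net.forward(x, train=False)
        pred = binarize(prob[:, 0], threshold)
        scores.extend(iou(pred[j], t[j, 0]) for j in range(len(chunk)))
    return float(np.mean(scores))


def train_fold(fold: int, pairs, split: FoldSplit, cfg: TrainConfig,
               model_cfg: ResUnetConfig, policy: AugmentationPolicy = None,
               seed: int = None):
    """Train one fold's network; returns (net with best weights, history).

    Trains on the other folds' slices (area-stratified augmentation applied
    if a policy is given), validates on this fold, stops when validation
    mean IoU stalls for ``cfg.patience`` epochs and restores the best epoch's
    weights.
    """
    if seed is None:
        seed = cfg.seed
    train_idx = split.train_indices(fold)
    val_idx = split.val_indices(fold)
    if not train_idx:
        raise ValueError(f"fold {fold}: empty training split")

    train_pairs = [pairs[i] for i in train_idx]
    if policy is not None:
        strat = stratify_by_area(train_pairs)
        train_pairs = augment_dataset(train_pairs, strat, policy)

    net = build_model(model_cfg, seed=seed)
    opt = Adam(net.parameters())
    rng = np.random.default_rng(seed + 1)
    stopper = EarlyStopping(cfg.patience)
    best_weights = net.get_weights()
    history = []
    step = 0

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(train_pairs))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            x, t = _batch_arrays(train_pairs, idx)
            prob = net.forward(x, train=True)
            losses.append(dice_loss(prob, t, cfg.dice_smooth))
            opt.zero_grad()
            net.backward(dice_loss_grad(prob, t, cfg.dice_smooth))
            opt.step(lr_at(step, cfg))
            step += 1
        val_iou = _mean_val_iou(net, pairs, val_idx, model_cfg.prob_threshold,
                                cfg.batch_size) if val_idx else float("nan")
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_mean_iou": val_iou, "lr": lr_at(step, cfg)})
        improved = val_iou > stopper.best
        stop = stopper.update(val_iou, epoch)
        if improved:
            best_weights = net.get_weights()
        if stop:
            break

    net.set_weights(best_weights)
    return net, pd.DataFrame(history)


def train_round(pairs, split: FoldSplit, cfg: TrainConfig,
                model_cfg: ResUnetConfig, policy: AugmentationPolicy = None,
                round_idx: int = 0):
    """Train the full cross-validation ensemble for one self-training round.

    Augmentation draws are refreshed per round and per fold (the policy seed
    is re-derived from the master seed, the round index and the fold), while
    the fold partition itself stays fixed across rounds.

    Returns (list of n_folds networks, list of history frames).
    """
    nets, histories = [], []
    for fold in range(split.n_folds):
        fold_seed = int(np.random.SeedSequence(
            cfg.seed, spawn_key=(round_idx, fold)).generate_state(1)[0] & 0x7FFFFFFF)
        fold_policy = None
        if policy is not None:
            fold_policy = dc_replace(policy, seed=fold_seed + 1)
        net, hist = train_fold(fold, pairs, split, cfg, model_cfg,
                               policy=fold_policy, seed=fold_seed)
        nets.append(net)
        histories.append(hist)
    return nets, histories
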