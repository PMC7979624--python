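"""Cross-validation training with AdamW and best-checkpoint selection.

Training runs fivefold cross-validation: the training cohort is split into
k near-equal folds, each fold in turn serving as the validation split.  An
epoch draws one random augmented crop from every training volume (batch
size is a single crop — volumetric inputs leave no memory for more).  The
learning rate decays exponentially, multiplied by ``lr_gamma`` every
``lr_step`` epochs.  Model selection monitors the mean foreground Dice on
full validation volumes, computed through the sliding-window inference
path, and keeps the best-scoring weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .augment import AugmentConfig, augment_sample
from .infer import InferenceConfig, argmax_labels, sliding_window_predict
from .losses_metrics import LossConfig, combined_loss, mean_foreground_dice
from .models import ModelConfig, SegModel, build_model
from .nn import AdamW, Tensor
from .preprocess import PreprocessConfig, downscale_labels_xy, preprocess_volume
from .volume_io import CTVolume, LabelMap

__all__ = [
    "OptimizerConfig", "CVPlan", "lr_at_epoch", "make_cv_splits",
    "TrainResult", "train_fold",
]


@dataclass
class OptimizerConfig:
    lr0: float = 1e-4
    lr_gamma: float = 0.95
    lr_step: int = 50
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-7
    weight_decay: float = 1e-4
    epochs: int = 300
    val_interval: int = 10
    seed: int = 0

    def __post_init__(self):
        if min(self.lr0, self.lr_gamma, self.lr_step, self.eps) <= 0:
            raise ValueError("learning-rate schedule parameters must be positive")
        if self.epochs < 0 or self.val_interval < 1:
            raise ValueError("epochs must be >= 0 and val_interval >= 1")


def lr_at_epoch(epoch: int, config: OptimizerConfig) -> float:
    """Exponentially decaying schedule: lr0 * gamma^floor(epoch / step)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return config.lr0 * config.lr_gamma ** (epoch // config.lr_step)


@dataclass
class CVPlan:
    k: int
    assignments: dict  # volume id -> fold index

    def fold_ids(self, fold: int) -> tuple[list, list]:
        """(train_ids, val_ids) for one fold."""
        train = [i for i, f in self.assignments.items() if f != fold]
        val = [i for i, f in self.assignments.items() if f == fold]
        return train, val


def make_cv_splits(ids: list, k: int = 5, seed: int = 0) -> CVPlan:
    """Deterministic shuffled partition into k folds of near-equal size."""
    ids = list(ids)
    if k < 1 or k > len(ids):
        raise ValueError(f"cannot split {len(ids)} ids into {k} folds")
    order = list(np.random.default_rng(seed).permutation(len(ids)))
    assignments = {ids[j]: i % k for i, j in enumerate(order)}
    return CVPlan(k=k, assignments=assignments)


@dataclass
class TrainResult:
    model: SegModel            # carries the best-validation weights
    log: pd.DataFrame          # per-epoch train loss; validation Dice where run
    best_epoch: int
    best_val_dice: float


def _validate(model: SegModel, val_set, pre: PreprocessConfig,
              infer_cfg: InferenceConfig) -> float:
    scores = []
    for ct, labels in val_set:
        probs = sliding_window_predict(model, ct, pre, infer_cfg)
        pred = argmax_labels(probs, spacing=ct.spacing)
        scores.append(mean_foreground_dice(pred, labels))
    return float(np.mean(scores))


def train_fold(train_set: list[tuple[CTVolume, LabelMap]],
               val_set: list[tuple[CTVolume, LabelMap]],
               model_config: ModelConfig,
               optimizer_config: OptimizerConfig | None = None,
               loss_config: LossConfig | None = None,
               augment_config: AugmentConfig | None = None,
               preprocess_config: PreprocessConfig | None = None,
               inference_config: InferenceConfig | None = None,
               verbose: bool = False) -> TrainResult:
    """Train one cross-validation fold and return the best checkpoint.

    ``train_set``/``val_set`` pair each CT with its (possibly sparsely
    annotated) label map; unannotated slices carry the ignore label and
    contribute nothing to loss or validation Dice.
    """
    opt_cfg = optimizer_config or OptimizerConfig()
    loss_cfg = loss_config or LossConfig()
    aug_cfg = augment_config or AugmentConfig()
    pre_cfg = preprocess_config or PreprocessConfig()
    inf_cfg = inference_config or InferenceConfig(
        window_slices=aug_cfg.crop_shape[0])

    model = build_model(model_config)
    opt = AdamW(model.parameters(), lr=opt_cfg.lr0, beta1=opt_cfg.beta1,
                beta2=opt_cfg.beta2, eps=opt_cfg.eps,
                weight_decay=opt_cfg.weight_decay)
    rng = np.random.default_rng(opt_cfg.seed)

    rows = []
    best_state = model.state_dict()
    best_dice = -math.inf
    best_epoch = -1
    for epoch in range(opt_cfg.epochs):
        opt.lr = lr_at_epoch(epoch, opt_cfg)
        order = rng.permutation(len(train_set))
        losses = []
        for idx in order:
            ct, labels = train_set[idx]
            ct_a, lab_a = augment_sample(ct, labels, aug_cfg, rng)
            x = preprocess_volume(ct_a, pre_cfg)
            y = downscale_labels_xy(lab_a.labels, pre_cfg.downscale_factor)
            model.zero_grad()
            loss = combined_loss(model(Tensor(x)), y, loss_cfg)
            loss.backward()
            opt.step()
            losses.append(float(loss.value))
        row = {"epoch": epoch, "lr": opt.lr, "train_loss": float(np.mean(losses)),
               "val_dice": np.nan}
        if (epoch + 1) % opt_cfg.val_interval == 0 or epoch == opt_cfg.epochs - 1:
            dice = _validate(model, val_set, pre_cfg, inf_cfg)
            if math.isnan(dice):
                raise RuntimeError(f"validation Dice is NaN at epoch {epoch}")
            row["val_dice"] = dice
            if dice > best_dice:
                best_dice = dice
                best_epoch = epoch
                best_state = model.state_dict()
            if verbose:
                print(f"epoch {epoch:4d}  lr {opt.lr:.2e}  "
                      f"loss {row['train_loss']:.4f}  val dice {dice:.4f}")
        rows.append(row)

    model.load_state_dict(best_state)
    if best_epoch < 0:  # zero epochs: return the initialization
        best_dice = float("nan")
    return TrainResult(model=model, log=pd.DataFrame(rows),
                       best_epoch=best_epoch, best_val_dice=best_dice)
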