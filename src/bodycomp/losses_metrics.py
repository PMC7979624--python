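"""Supervision losses with ignore-label exclusion, and evaluation metrics.

The training loss is an equally weighted sum of softmax cross-entropy and a
generalized Sørensen Dice loss computed on probabilities:

    L_XCE  = -(1/N) sum_n sum_c y_{c,n} log(p_{c,n})
    L_Dice = 1 - 1/(C-1) * sum_{c>0} (sum_n 2 p_{c,n} y_{c,n} + eps)
                                     / (sum_n p_{c,n} + y_{c,n} + eps)
    L_SV   = 0.5 * L_XCE + 0.5 * L_Dice

with N the number of annotated (non-ignore) voxels.  The background class
is excluded from the Dice term so the foreground regions carry more weight;
voxels with the ignore label contribute neither value nor gradient to
either loss.

Evaluation side: hard per-class Dice scores, intra-class correlation
(two-way random effects, absolute agreement, single measurement — ICC(2,1))
and Bland-Altman agreement statistics for per-slice tissue volumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .nn.autograd import Tensor, accumulate_grad, make_op
from .volume_io import IGNORE, N_CLASSES, LabelMap

__all__ = [
    "LossConfig", "xce_loss", "generalized_dice_loss", "combined_loss",
    "dice_score", "mean_foreground_dice", "icc", "BlandAltman", "bland_altman",
]


@dataclass
class LossConfig:
    epsilon: float = 1e-5
    w_xce: float = 0.5
    w_dice: float = 0.5
    background_index: int = 0

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if abs(self.w_xce + self.w_dice - 1.0) > 1e-9:
            raise ValueError("loss weights must sum to 1")


def _labels_array(labels) -> np.ndarray:
    return labels.labels if isinstance(labels, LabelMap) else np.asarray(labels)


def _prepare(probs_shape, labels) -> tuple[np.ndarray, np.ndarray]:
    """One-hot ground truth (C, ...) and boolean valid mask (...)."""
    lab = _labels_array(labels)
    c = probs_shape[0]
    if lab.shape != tuple(probs_shape[1:]):
        raise ValueError(f"label shape {lab.shape} does not match "
                         f"probability grid {tuple(probs_shape[1:])}")
    valid = lab != IGNORE
    onehot = np.zeros(probs_shape, dtype=np.float32)
    if valid.any():
        idx = np.nonzero(valid)
        onehot[(lab[valid].astype(np.intp),) + idx] = 1.0
    return onehot, valid


def xce_loss(probs, labels):
    """Softmax cross-entropy averaged over annotated voxels.

    Accepts a plain array (returns float) or an autograd Tensor (returns a
    scalar Tensor wired for backpropagation).
    """
    is_tensor = isinstance(probs, Tensor)
    p = probs.value if is_tensor else np.asarray(probs, dtype=np.float32)
    onehot, valid = _prepare(p.shape, labels)
    n = int(valid.sum())
    if n == 0:
        warnings.warn("all voxels carry the ignore label; cross-entropy is 0")
        if is_tensor:
            return make_op(np.float32(0.0), (probs,), lambda g: None)
        return 0.0
    pc = np.clip(p, 1e-12, None)
    value = float(-(onehot * np.log(pc)).sum() / n)
    if not is_tensor:
        return value

    def backward(grad):
        if probs.requires_grad:
            accumulate_grad(probs, grad * (-onehot / (pc * n)))

    return make_op(np.float32(value), (probs,), backward)


def generalized_dice_loss(probs, labels, config: LossConfig | None = None):
    """Soft Dice loss averaged over the foreground classes only.

    Ignored voxels are excluded from every sum; a foreground class absent
    from both prediction mass and truth contributes eps/eps = 1 (no
    penalty).  Returns float for arrays, scalar Tensor for Tensors.
    """
    config = config or LossConfig()
    is_tensor = isinstance(probs, Tensor)
    p = probs.value if is_tensor else np.asarray(probs, dtype=np.float32)
    onehot, valid = _prepare(p.shape, labels)
    c = p.shape[0]
    eps = config.epsilon
    fg = [k for k in range(c) if k != config.background_index]

    pv = p.reshape(c, -1)[:, valid.ravel()]
    yv = onehot.reshape(c, -1)[:, valid.ravel()]
    num = 2.0 * (pv[fg] * yv[fg]).sum(axis=1) + eps
    den = (pv[fg] + yv[fg]).sum(axis=1) + eps
    value = float(1.0 - (num / den).mean())
    if not is_tensor:
        return value

    def backward(grad):
        if not probs.requires_grad:
            return
        dp = np.zeros_like(p)
        vmask = valid
        for i, k in enumerate(fg):
            # d(num_k/den_k)/dp_k = (2 y den - num) / den^2 on valid voxels
            dterm = (2.0 * onehot[k] * den[i] - num[i]) / den[i] ** 2
            dp[k] = np.where(vmask, -dterm / len(fg), 0.0)
        accumulate_grad(probs, grad * dp)

    return make_op(np.float32(value), (probs,), backward)


def combined_loss(probs, labels, config: LossConfig | None = None):
    """The supervision loss: weighted sum of cross-entropy and Dice terms."""
    config = config or LossConfig()
    x = xce_loss(probs, labels)
    d = generalized_dice_loss(probs, labels, config)
    if isinstance(probs, Tensor):
        def back(grad):
            if x.requires_grad:
                accumulate_grad(x, grad * np.float32(config.w_xce))
            if d.requires_grad:
                accumulate_grad(d, grad * np.float32(config.w_dice))
        val = np.float32(config.w_xce * float(x.value) + config.w_dice * float(d.value))
        return make_op(val, (x, d), back)
    return config.w_xce * x + config.w_dice * d


# ---------------------------------------------------------------------------
# evaluation metrics

def dice_score(pred, truth, class_code: int) -> float:
    """Hard Sørensen Dice 2|P∩T|/(|P|+|T|) over annotated voxels.

    Defined as 1.0 when the class is absent from both maps.
    """
    if class_code not in range(N_CLASSES):
        raise ValueError(f"unknown class code {class_code}")
    pa = _labels_array(pred)
    ta = _labels_array(truth)
    if pa.shape != ta.shape:
        raise ValueError(f"shape mismatch {pa.shape} vs {ta.shape}")
    valid = (ta != IGNORE) & (pa != IGNORE)
    p = (pa == class_code) & valid
    t = (ta == class_code) & valid
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & t).sum()) / denom


def mean_foreground_dice(pred, truth) -> float:
    """Mean Dice over the five foreground region classes."""
    return float(np.mean([dice_score(pred, truth, c) for c in range(1, N_CLASSES)]))


def icc(series_a, series_b, form: str = "ICC2") -> float:
    """Intra-class correlation between two measurement series.

    Default form is ICC(2,1): two-way random effects, absolute agreement,
    single measurement — the appropriate form for judging whether an
    automatic volumetry reproduces ground-truth volumes including any bias.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1D and of equal length")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 paired measurements")
    if np.var(a) == 0 and np.var(b) == 0 and np.all(a == b[0]):
        raise ValueError("ICC undefined: no variance in either series")
    import pandas as pd
    import pingouin as pg
    df = pd.DataFrame({
        "targets": np.tile(np.arange(n), 2),
        "raters": np.repeat(["a", "b"], n),
        "scores": np.concatenate([a, b]),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pg.intraclass_corr(data=df, targets="targets", raters="raters",
                                 ratings="scores")
    # pingouin labels the six forms either ICC1..ICC3k or ICC(1,1)..ICC(C,k)
    aliases = {"ICC1": ["ICC1", "ICC(1,1)"], "ICC2": ["ICC2", "ICC(A,1)"],
               "ICC3": ["ICC3", "ICC(C,1)"]}
    wanted = aliases.get(form, [form])
    rows = res[res["Type"].isin(wanted)]
    if rows.empty:
        raise ValueError(f"unknown ICC form {form!r}; available: {res['Type'].tolist()}")
    value = float(rows["ICC"].iloc[0])
    if not np.isfinite(value):
        raise ValueError("ICC undefined for the given series")
    return value


@dataclass
class BlandAltman:
    """Mean difference and 95% limits of agreement between two series."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float


def bland_altman(series_a, series_b) -> BlandAltman:
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1D and of equal length")
    d = a - b
    md = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return BlandAltman(md, sd, md - 1.96 * sd, md + 1.96 * sd)
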