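"""Full-volume prediction: sliding z-window with weighted blending, plus
fold-ensemble probability averaging.

Inference keeps the full in-plane field of view (no cropping); the volume
is processed in overlapping windows of 32 axial slices with 75% overlap
(stride 8).  Overlapping predictions are blended with a center-weighted
profile so that slices near a window border — where the network has less
3D context — contribute less.  Probabilities from the cross-validation
fold models are averaged into an ensemble field, and hard labels are the
per-voxel argmax (ties resolved toward the lowest class index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import SegModel
from .nn.functional import upsample_linear_axis
from .preprocess import PreprocessConfig, downscale_xy, stack_and_center
from .volume_io import HU_MIN, CTVolume, LabelMap

__all__ = [
    "InferenceConfig", "plan_windows", "window_weights",
    "sliding_window_predict", "ensemble_predict", "argmax_labels",
]


@dataclass
class InferenceConfig:
    window_slices: int = 32
    overlap_fraction: float = 0.75
    weighting: str = "triangular"  # uniform | triangular | gaussian

    def __post_init__(self):
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.stride < 1:
            raise ValueError("overlap too large: stride would be < 1 slice")
        if self.weighting not in ("uniform", "triangular", "gaussian"):
            raise ValueError(f"unknown weighting {self.weighting!r}")

    @property
    def stride(self) -> int:
        return int(round(self.window_slices * (1.0 - self.overlap_fraction)))


def plan_windows(n_slices: int, config: InferenceConfig | None = None) -> list[int]:
    """Start indices of the sliding windows covering ``n_slices``.

    Starts advance by the stride; the final window is end-aligned so the
    last slice is always covered.  Volumes shorter than one window get a
    single window at 0 (the predictor pads).
    """
    config = config or InferenceConfig()
    ws = config.window_slices
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if n_slices <= ws:
        return [0]
    starts = list(range(0, n_slices - ws + 1, config.stride))
    if starts[-1] + ws < n_slices:
        starts.append(n_slices - ws)
    return starts


def window_weights(config: InferenceConfig | None = None) -> np.ndarray:
    """Strictly positive per-slice blending weights within one window."""
    config = config or InferenceConfig()
    ws = config.window_slices
    if config.weighting == "uniform":
        return np.ones(ws)
    i = np.arange(ws)
    if config.weighting == "triangular":
        return 1.0 + np.minimum(i, ws - 1 - i)
    center = (ws - 1) / 2.0
    return np.exp(-0.5 * ((i - center) / (ws / 4.0)) ** 2)


def _pad_inplane(x: np.ndarray, multiple: int) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = x.shape[-2:]
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph or pw:
        x = np.pad(x, [(0, 0)] * (x.ndim - 2) + [(0, ph), (0, pw)], mode="reflect")
    return x, (ph, pw)


def sliding_window_predict(model: SegModel, ct: CTVolume,
                           pre: PreprocessConfig | None = None,
                           config: InferenceConfig | None = None) -> np.ndarray:
    """Probability field (C, z, y, x) for a whole volume at native resolution.

    Each window is windowed/stacked/downscaled exactly as in training,
    predicted, and accumulated as sum(w_z * p) / sum(w_z) per voxel.  The
    class probabilities are then upsampled back to the native in-plane grid
    and renormalized to a simplex.
    """
    pre = pre or PreprocessConfig()
    config = config or InferenceConfig()
    ws = config.window_slices
    depth = model.config.depth
    if ws % 2 ** depth:
        raise ValueError(f"window_slices={ws} must be divisible by 2^depth={2**depth}")

    nz, h, w = ct.shape
    hu = ct.voxels
    if nz < ws:  # pad the cranial end with air
        hu = np.pad(hu, ((0, ws - nz), (0, 0), (0, 0)), constant_values=HU_MIN)
    x = stack_and_center(hu, pre)
    x = downscale_xy(x, pre.downscale_factor)
    x, (ph, pw) = _pad_inplane(x, 2 ** depth)

    nzp = x.shape[1]
    c = model.config.n_classes
    acc = np.zeros((c, nzp) + x.shape[2:], dtype=np.float64)
    wsum = np.zeros(nzp, dtype=np.float64)
    weights = window_weights(config)
    for start in plan_windows(nzp, config):
        probs = model.predict_proba(x[:, start:start + ws])
        acc[:, start:start + ws] += probs * weights[None, :, None, None]
        wsum[start:start + ws] += weights
    acc /= wsum[None, :, None, None]

    acc = acc[:, :nz]
    if ph or pw:  # padding was applied at the downscaled resolution
        hds, wds = acc.shape[-2:]
        acc = acc[..., :hds - ph, :wds - pw]
    # back to native in-plane resolution
    f = pre.downscale_factor
    out = acc.astype(np.float32)
    if f > 1:
        if f & (f - 1):
            from scipy import ndimage
            out = ndimage.zoom(out, (1, 1, f, f), order=1, prefilter=False)
        else:
            times = int(np.log2(f))
            out = upsample_linear_axis(out, axis=2, times=times)
            out = upsample_linear_axis(out, axis=3, times=times)
    out = out[..., :h, :w]
    out /= out.sum(axis=0, keepdims=True)
    return out.astype(np.float32)


def ensemble_predict(models: list[SegModel], ct: CTVolume,
                     pre: PreprocessConfig | None = None,
                     config: InferenceConfig | None = None) -> np.ndarray:
    """Unweighted mean of the fold models' probability fields."""
    if not models:
        raise ValueError("need at least one model")
    ncls = {m.config.n_classes for m in models}
    if len(ncls) != 1:
        raise ValueError(f"models disagree on class count: {sorted(ncls)}")
    acc = None
    for m in models:
        p = sliding_window_predict(m, ct, pre, config)
        acc = p if acc is None else acc + p
    return (acc / len(models)).astype(np.float32)


def argmax_labels(probs: np.ndarray,
                  spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> LabelMap:
    """Hard labels: per-voxel class of maximal probability (lowest index wins ties)."""
    probs = np.asarray(probs)
    if probs.ndim != 4:
        raise ValueError(f"expected (C, z, y, x) field, got shape {probs.shape}")
    return LabelMap(labels=np.argmax(probs, axis=0).astype(np.uint8), spacing=spacing)
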