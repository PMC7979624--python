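"""HU windowing, channel stacking and in-plane downscaling.

A network input is built from a CT volume by mapping the HU grid through
one or more HU windows (each clipped to [0, 1]), stacking the windows as
channels, recentring to [-1, 1] and downscaling the in-plane axes.  The
default configuration stacks the full 12-bit scanner range, an abdomen
window and a liver window — the multi-window setup that performed best in
the ablation over window choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume_io import CTVolume

__all__ = [
    "WindowSpec", "PreprocessConfig", "ABLATION_WINDOW_CONFIGS",
    "hu_window_normalize", "stack_and_center", "downscale_xy", "downscale_labels_xy",
    "preprocess_volume",
]


@dataclass(frozen=True)
class WindowSpec:
    """An HU window [lo, hi]; values outside are clipped."""

    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"degenerate window: lo={self.lo} must be < hi={self.hi}")


FULL_RANGE = WindowSpec(-1024, 3071)
ABDOMEN = WindowSpec(-150, 250)
LIVER = WindowSpec(-95, 155)


def _default_windows() -> tuple[WindowSpec, ...]:
    return (FULL_RANGE, ABDOMEN, LIVER)


@dataclass
class PreprocessConfig:
    windows: tuple[WindowSpec, ...] = field(default_factory=_default_windows)
    downscale_factor: int = 2

    def __post_init__(self):
        self.windows = tuple(self.windows)
        if len(self.windows) < 1:
            raise ValueError("at least one HU window is required")
        if self.downscale_factor < 1:
            raise ValueError("downscale_factor must be >= 1")

    @property
    def n_channels(self) -> int:
        return len(self.windows)


#: The window configurations compared in the ablation over HU mappings,
#: selectable by name from the run config.
ABLATION_WINDOW_CONFIGS: dict[str, tuple[WindowSpec, ...]] = {
    "multi_window": _default_windows(),
    "full_range": (FULL_RANGE,),
    "half_range": (WindowSpec(-1024, 2047),),
    "quarter_range": (WindowSpec(-1024, 1023),),
    "abdomen": (ABDOMEN,),
}


def hu_window_normalize(volume: CTVolume | np.ndarray, window: WindowSpec) -> np.ndarray:
    """Map HU through ``window`` to [0, 1], clipping outliers.

    ``v -> clip((v - lo) / (hi - lo), 0, 1)``; monotone non-decreasing in HU.
    """
    hu = volume.voxels if isinstance(volume, CTVolume) else np.asarray(volume)
    out = (hu.astype(np.float32) - window.lo) / (window.hi - window.lo)
    return np.clip(out, 0.0, 1.0)


def stack_and_center(volume: CTVolume | np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Stack windowed copies as channels and recenter to [-1, 1].

    Channel c equals ``2 * hu_window_normalize(volume, windows[c]) - 1``;
    output shape is ``(n_windows, z, y, x)``.
    """
    chans = [2.0 * hu_window_normalize(volume, w) - 1.0 for w in config.windows]
    return np.stack(chans, axis=0).astype(np.float32)


def downscale_xy(grid: np.ndarray, factor: int) -> np.ndarray:
    """Downscale the two in-plane axes by block averaging.

    Works on ``(..., y, x)`` arrays; the z (and channel) extent is kept.
    In-plane dims must be divisible by ``factor`` — callers pad first.
    """
    if factor == 1:
        return np.asarray(grid)
    g = np.asarray(grid)
    *lead, h, w = g.shape
    if h % factor or w % factor:
        raise ValueError(f"in-plane dims {(h, w)} not divisible by factor {factor}")
    g = g.reshape(*lead, h // factor, factor, w // factor, factor)
    return g.mean(axis=(-3, -1), dtype=np.float32)


def downscale_labels_xy(labels: np.ndarray, factor: int) -> np.ndarray:
    """Downscale a label grid by nearest-neighbour sampling.

    Takes the top-left voxel of each block; class codes are never averaged,
    and an ignore voxel at the sampled position propagates.
    """
    if factor == 1:
        return np.asarray(labels)
    lab = np.asarray(labels)
    h, w = lab.shape[-2:]
    if h % factor or w % factor:
        raise ValueError(f"in-plane dims {(h, w)} not divisible by factor {factor}")
    return lab[..., ::factor, ::factor]


def preprocess_volume(volume: CTVolume | np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Full input pipeline: window, stack, center, downscale in-plane."""
    x = stack_and_center(volume, config)
    return downscale_xy(x, config.downscale_factor)
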