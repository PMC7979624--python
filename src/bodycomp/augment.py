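"""Training-time augmentation: in-plane scaling, x-mirroring, random crops.

Exactly three augmentations are applied, in this order: anisotropic
in-plane scaling (independent uniform factors for y and x, acting also as
an aspect-ratio augmentation), mirroring along the x axis with probability
0.5, and random cropping of a fixed-size subvolume.  Images are
interpolated linearly, label maps by nearest neighbour so class codes are
never mixed.  Volumes thinner than the crop are zero-padded with air HU
(-1024) and ignore labels before cropping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import HU_MIN, IGNORE, CTVolume, LabelMap

__all__ = ["AugmentConfig", "augment_sample"]


@dataclass
class AugmentConfig:
    scale_lo: float = 0.8
    scale_hi: float = 1.2
    flip_x: bool = True
    crop_shape: tuple[int, int, int] = (32, 256, 256)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.scale_lo <= self.scale_hi:
            raise ValueError("need 0 < scale_lo <= scale_hi")
        if any(c < 1 for c in self.crop_shape):
            raise ValueError("crop_shape must be positive")


def _resize_inplane(grid: np.ndarray, sy: float, sx: float, order: int,
                    cval: float) -> np.ndarray:
    h, w = grid.shape[1:]
    nh, nw = max(1, round(h * sy)), max(1, round(w * sx))
    if (nh, nw) == (h, w):
        return grid
    return ndimage.zoom(grid, (1.0, nh / h, nw / w), order=order, mode="grid-constant",
                        cval=cval, grid_mode=True, prefilter=False)


def augment_sample(ct: CTVolume, labels: LabelMap, config: AugmentConfig,
                   rng: np.random.Generator) -> tuple[CTVolume, LabelMap]:
    """One augmented training sample; identical rng state gives identical output."""
    if ct.shape != labels.shape:
        raise ValueError(f"CT shape {ct.shape} != label shape {labels.shape}")
    sy = rng.uniform(config.scale_lo, config.scale_hi)
    sx = rng.uniform(config.scale_lo, config.scale_hi)
    hu = _resize_inplane(ct.voxels.astype(np.float32), sy, sx, order=1, cval=HU_MIN)
    lab = _resize_inplane(labels.labels, sy, sx, order=0, cval=IGNORE)

    if config.flip_x and rng.random() < 0.5:
        hu = hu[:, :, ::-1]
        lab = lab[:, :, ::-1]

    cz, cyy, cxx = config.crop_shape
    pads = [max(0, c - s) for c, s in zip(config.crop_shape, hu.shape)]
    if any(pads):
        pad_spec = [(p // 2, p - p // 2) for p in pads]
        hu = np.pad(hu, pad_spec, constant_values=HU_MIN)
        lab = np.pad(lab, pad_spec, constant_values=IGNORE)

    starts = [rng.integers(0, s - c + 1) for s, c in zip(hu.shape, (cz, cyy, cxx))]
    sl = tuple(slice(a, a + c) for a, c in zip(starts, (cz, cyy, cxx)))
    dz, dy, dx = ct.spacing
    spacing = (dz, dy / sy, dx / sx)
    return (CTVolume(voxels=np.rint(hu[sl]), spacing=spacing),
            LabelMap(labels=lab[sl], spacing=spacing))
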