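"""The two 3D segmentation architectures and their parameter accounting.

Both networks share one skeleton: an encoder of ``depth`` max-pooling
stages, a decoder of ``depth`` upsampling stages with skip connections, and
a biased 1x1x1 classification head with per-voxel softmax over the six
region classes.  Feature width at level d is ``n_f * 2**d``.  All interior
convolutions are bias-free and followed by instance normalization (batch
size is a single volume crop, so batch statistics are unavailable) and
ReLU.  Upsampling is trilinear interpolation followed by a bias-free 1x1x1
channel projection; the 3x3x3 convolutions of the level block then fuse the
upsampled features with the skip path.  Transposed convolutions are avoided
because of their checkerboard artifacts.

``unet3d`` uses plain blocks of two successive 3x3x3 convolutions with
identity skips.  ``multires_unet3d`` replaces each block with a
multi-resolution block — three chained 3x3x3 convolutions of widths
``int(W/6), int(W/3), int(W/2)`` (W = alpha * level width) whose outputs
are concatenated and summed with a 1x1x1 residual shortcut — and each skip
with a residual path of ``depth - level`` conv/shortcut units.  The width
multiplier defaults to alpha = 1.95, the value at which the trainable
parameter budgets of the published configurations are reproduced (see
docs/methods.md for the derivation and the one printed count that no
channel-scaling architecture can reach).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .nn import functional as F

__all__ = [
    "ModelConfig", "SegModel", "UNet3D", "MultiResUNet3D",
    "build_model", "count_parameters", "save_checkpoint", "load_checkpoint",
    "multires_widths",
]


@dataclass
class ModelConfig:
    family: str = "multires_unet3d"
    n_f: int = 16
    depth: int = 4
    in_channels: int = 3
    n_classes: int = 6
    alpha: float = 1.95
    seed: int = 0

    def __post_init__(self):
        if self.family not in ("unet3d", "multires_unet3d"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.n_f < 1 or self.depth < 1:
            raise ValueError("n_f and depth must be positive")

    def level_width(self, d: int) -> int:
        return self.n_f * 2 ** d


def multires_widths(level_width: int, alpha: float) -> tuple[int, int, int]:
    """Widths of the three chained convolutions in a multi-resolution block."""
    w = alpha * level_width
    return max(1, int(w / 6)), max(1, int(w / 3)), max(1, int(w / 2))


# ---------------------------------------------------------------------------
# blocks

class DoubleConvBlock(nn.Module):
    """Two successive 3x3x3 conv + instance norm + ReLU units."""

    def __init__(self, cin: int, f: int, rng):
        self.c1 = nn.ConvNormAct(cin, f, 3, rng)
        self.c2 = nn.ConvNormAct(f, f, 3, rng)
        self.out_channels = f

    def __call__(self, x):
        return self.c2(self.c1(x))


class MultiResBlock(nn.Module):
    """Chained multi-scale convolutions with a 1x1x1 residual shortcut.

    The three 3x3x3 convolutions approximate receptive fields of 3, 5 and 7
    voxels; their outputs are concatenated and added to a projected shortcut
    of the block input.
    """

    def __init__(self, cin: int, level_width: int, alpha: float, rng):
        f1, f2, f3 = multires_widths(level_width, alpha)
        self.out_channels = f1 + f2 + f3
        self.shortcut = nn.ConvNormAct(cin, self.out_channels, 1, rng, act=False)
        self.c1 = nn.ConvNormAct(cin, f1, 3, rng)
        self.c2 = nn.ConvNormAct(f1, f2, 3, rng)
        self.c3 = nn.ConvNormAct(f2, f3, 3, rng)

    def __call__(self, x):
        s = self.shortcut(x)
        a = self.c1(x)
        b = self.c2(a)
        c = self.c3(b)
        out = F.concat_channels([a, b, c])
        return F.relu(F.add(out, s))


class ResPathUnit(nn.Module):
    """One residual-path element: 3x3x3 conv plus 1x1x1 shortcut, summed."""

    def __init__(self, cin: int, f: int, rng):
        self.main = nn.ConvNormAct(cin, f, 3, rng, act=False)
        self.shortcut = nn.ConvNormAct(cin, f, 1, rng, act=False)

    def __call__(self, x):
        return F.relu(F.add(self.main(x), self.shortcut(x)))


class ResPath(nn.Module):
    """Chain of residual-path units carried along a skip connection."""

    def __init__(self, cin: int, f: int, length: int, rng):
        units = []
        c = cin
        for _ in range(length):
            units.append(ResPathUnit(c, f, rng))
            c = f
        self.units = units
        self.out_channels = c

    def __call__(self, x):
        for u in self.units:
            x = u(x)
        return x


class UpProject(nn.Module):
    """Trilinear factor-2 upsampling followed by a 1x1x1 channel projection."""

    def __init__(self, cin: int, f: int, rng):
        self.proj = nn.Conv3d(cin, f, 1, bias=False, rng=rng)

    def __call__(self, x):
        return self.proj(F.upsample3d(x))


# ---------------------------------------------------------------------------
# networks

class SegModel(nn.Module):
    """Common scaffolding: forward on logits, softmax prediction, shape checks."""

    config: ModelConfig

    def forward_logits(self, x: nn.Tensor) -> nn.Tensor:
        raise NotImplementedError

    def _check_input(self, x) -> None:
        c = x.shape[0]
        if c != self.config.in_channels:
            raise ValueError(f"expected {self.config.in_channels} channels, got {c}")
        div = 2 ** self.config.depth
        for n, ax in zip(x.shape[1:], "zyx"):
            if n % div:
                raise ValueError(
                    f"spatial dim {ax}={n} not divisible by 2^depth={div}")

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        """Per-voxel class probabilities (softmax over channel axis)."""
        return F.softmax_channels(self.forward_logits(x))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Inference path: no tape, input array, probability array out."""
        with nn.no_grad():
            return self(nn.Tensor(x)).value


class UNet3D(SegModel):
    def __init__(self, config: ModelConfig):
        if config.family != "unet3d":
            raise ValueError("config.family must be 'unet3d'")
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.depth
        self.enc = []
        c = config.in_channels
        for lvl in range(d + 1):
            blk = DoubleConvBlock(c, config.level_width(lvl), rng)
            self.enc.append(blk)
            c = blk.out_channels
        self.up = []
        self.dec = []
        for lvl in range(d - 1, -1, -1):
            f = config.level_width(lvl)
            self.up.append(UpProject(c, f, rng))
            blk = DoubleConvBlock(2 * f, f, rng)
            self.dec.append(blk)
            c = blk.out_channels
        self.head = nn.Conv3d(c, config.n_classes, 1, bias=True, rng=rng)

    def forward_logits(self, x: nn.Tensor) -> nn.Tensor:
        self._check_input(x)
        skips = []
        for blk in self.enc[:-1]:
            x = blk(x)
            skips.append(x)
            x = F.max_pool3d(x)
        x = self.enc[-1](x)
        for up, blk, skip in zip(self.up, self.dec, reversed(skips)):
            x = blk(F.concat_channels([up(x), skip]))
        return self.head(x)


class MultiResUNet3D(SegModel):
    def __init__(self, config: ModelConfig):
        if config.family != "multires_unet3d":
            raise ValueError("config.family must be 'multires_unet3d'")
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.depth
        self.enc = []
        self.paths = []
        c = config.in_channels
        for lvl in range(d + 1):
            blk = MultiResBlock(c, config.level_width(lvl), config.alpha, rng)
            self.enc.append(blk)
            if lvl < d:
                self.paths.append(
                    ResPath(blk.out_channels, config.level_width(lvl), d - lvl, rng))
            c = blk.out_channels
        self.up = []
        self.dec = []
        for lvl in range(d - 1, -1, -1):
            f = config.level_width(lvl)
            self.up.append(UpProject(c, f, rng))
            blk = MultiResBlock(f + self.paths[lvl].out_channels,
                                config.level_width(lvl), config.alpha, rng)
            self.dec.append(blk)
            c = blk.out_channels
        self.head = nn.Conv3d(c, config.n_classes, 1, bias=True, rng=rng)

    def forward_logits(self, x: nn.Tensor) -> nn.Tensor:
        self._check_input(x)
        skips = []
        for lvl, blk in enumerate(self.enc[:-1]):
            x = blk(x)
            skips.append(self.paths[lvl](x))
            x = F.max_pool3d(x)
        x = self.enc[-1](x)
        for up, blk, skip in zip(self.up, self.dec, reversed(skips)):
            x = blk(F.concat_channels([up(x), skip]))
        return self.head(x)


# ---------------------------------------------------------------------------
# factory / accounting / checkpoints

def build_model(config: ModelConfig) -> SegModel:
    if config.family == "unet3d":
        return UNet3D(config)
    return MultiResUNet3D(config)


def count_parameters(model: SegModel) -> int:
    """Total size of all trainable weight containers."""
    return int(sum(p.value.size for p in model.parameters()))


def save_checkpoint(model: SegModel, path: str) -> None:
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path: str) -> SegModel:
    with np.load(path) as data:
        cfg = ModelConfig(**json.loads(bytes(data["__config__"]).decode()))
        model = build_model(cfg)
        model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model
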