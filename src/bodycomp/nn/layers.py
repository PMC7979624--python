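"""Parameterized layers built on the autograd primitives."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from . import functional as F

__all__ = ["Param", "Module", "Conv3d", "InstanceNorm3d", "ConvNormAct"]


class Param(Tensor):
    """A trainable tensor."""

    def __init__(self, value):
        super().__init__(value, requires_grad=True)


class Module:
    """Base class: recursive parameter collection and (de)serialization."""

    def parameters(self) -> list[Param]:
        out: list[Param] = []
        for v in vars(self).values():
            out.extend(_collect(v))
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Param]]:
        out: list[tuple[str, Param]] = []
        for name, v in vars(self).items():
            out.extend(_collect_named(v, f"{prefix}{name}"))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.value.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)}, unexpected={sorted(extra)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != p.value.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.value.shape}")
            p.value = arr.copy()


def _collect(v):
    if isinstance(v, Param):
        return [v]
    if isinstance(v, Module):
        return v.parameters()
    if isinstance(v, (list, tuple)):
        out = []
        for item in v:
            out.extend(_collect(item))
        return out
    return []


def _collect_named(v, name):
    if isinstance(v, Param):
        return [(name, v)]
    if isinstance(v, Module):
        return v.named_parameters(prefix=name + ".")
    if isinstance(v, (list, tuple)):
        out = []
        for i, item in enumerate(v):
            out.extend(_collect_named(item, f"{name}.{i}"))
        return out
    return []


class Conv3d(Module):
    """3D convolution, stride 1, same padding, He-normal initialization.

    Convolutions that feed an instance-norm layer are bias-free; the final
    classification head keeps its bias.
    """

    def __init__(self, cin: int, cout: int, k: int, bias: bool, rng: np.random.Generator):
        fan_in = cin * k ** 3
        std = np.sqrt(2.0 / fan_in)
        self.weight = Param(rng.normal(0.0, std, size=(cout, cin, k, k, k)))
        self.bias = Param(np.zeros(cout)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return F.conv3d(x, self.weight, self.bias)


class InstanceNorm3d(Module):
    def __init__(self, c: int):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))

    def __call__(self, x: Tensor) -> Tensor:
        return F.instance_norm(x, self.gamma, self.beta)


class ConvNormAct(Module):
    """conv3 -> instance norm -> optional ReLU, the workhorse block unit."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 act: bool = True):
        self.conv = Conv3d(cin, cout, k, bias=False, rng=rng)
        self.norm = InstanceNorm3d(cout)
        self.act = act

    def __call__(self, x: Tensor) -> Tensor:
        y = self.norm(self.conv(x))
        return F.relu(y) if self.act else y
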