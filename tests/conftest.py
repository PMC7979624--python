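"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from bodycomp.phantom import PhantomConfig, generate_phantom


# ---------------------------------------------------------------------------
# independent analytic parameter-count oracle
#
# Walks the documented architecture layer by layer with the closed-form
# per-layer sizes (bias-free conv: k^3*c_in*c_out; biased conv adds c_out;
# instance norm: 2*c).  Written without reference to the model classes so it
# can catch structural mistakes in them.

def _conv(cin, cout, k, bias=False):
    return k ** 3 * cin * cout + (cout if bias else 0)


def _norm(c):
    return 2 * c


def _mres_widths(u, alpha):
    w = alpha * u
    return max(1, int(w / 6)), max(1, int(w / 3)), max(1, int(w / 2))


def analytic_param_count(family: str, n_f: int, depth: int = 4,
                         in_channels: int = 3, n_classes: int = 6,
                         alpha: float = 1.95) -> int:
    """Expected trainable parameter count, derived layer by layer."""
    widths = [n_f * 2 ** d for d in range(depth + 1)]
    total = 0

    def plain_block(cin, f):
        return (_conv(cin, f, 3) + _norm(f)) + (_conv(f, f, 3) + _norm(f)), f

    def mres_block(cin, u):
        f1, f2, f3 = _mres_widths(u, alpha)
        out = f1 + f2 + f3
        n = _conv(cin, out, 1) + _norm(out)            # residual shortcut
        n += _conv(cin, f1, 3) + _norm(f1)
        n += _conv(f1, f2, 3) + _norm(f2)
        n += _conv(f2, f3, 3) + _norm(f3)
        return n, out

    block = plain_block if family == "unet3d" else \
        lambda cin, u: mres_block(cin, u)

    c = in_channels
    enc_out = []
    for d in range(depth + 1):
        n, c = block(c, widths[d])
        total += n
        enc_out.append(c)

    skip_out = list(enc_out[:depth])
    if family == "multires_unet3d":
        for d in range(depth):
            c_in, f = enc_out[d], widths[d]
            for _ in range(depth - d):  # residual path chain
                total += _conv(c_in, f, 3) + _norm(f)
                total += _conv(c_in, f, 1) + _norm(f)
                c_in = f
            skip_out[d] = f

    c = enc_out[depth]
    for d in range(depth - 1, -1, -1):
        f = widths[d]
        total += _conv(c, f, 1)                        # upsample projection
        n, c = block(f + skip_out[d], widths[d])
        total += n
    total += _conv(c, n_classes, 1, bias=True)         # classification head
    return total


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def small_phantom():
    """A 10x32x32 phantom with truth, shared read-only across tests."""
    cfg = PhantomConfig(shape=(10, 32, 32), spacing=(5.0, 12.5, 12.5), seed=7)
    return generate_phantom(cfg, seed=7)


@pytest.fixture(scope="session")
def default_phantom():
    """The default 20x64x64 phantom used by the volumetry tests."""
    return generate_phantom(PhantomConfig(seed=3), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
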