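"""Backbone/neck building blocks.

Baseline blocks (``Conv``-BN-SiLU unit, ``C2f``, ``SPPF``) follow the
YOLOv8 topology so the reference profile is reproducible.  The DR family
replaces C2f at all eight sites:

* ``DilatedReparamBlock`` (see :mod:`citrusdet.reparam`): parallel dilated
  depthwise branches mergeable into one 9x9 depthwise conv.
* ``DRBNBottleneck``: a residual bottleneck whose spatial mixing is a dense
  3x3 conv followed by the 9x9 dilated-reparam depthwise conv.
* ``DRBNCSP``: CSP split (two 1x1 reductions to a hidden width, a stack of
  DRBNBottlenecks on one path, concat, 1x1 fuse) in the GELAN style.
* ``DRModule``: 1x1 in-conv to ``c3`` channels, channel chunk into halves,
  two sequential stages (DRBNCSP to ``c4`` then a 3x3 stage conv to ``c5``),
  concatenation of the two chunk halves with both stage outputs, 1x1
  out-conv.

Stage widths (c3, c4, c5, repeats) are free hyper-parameters fixed per
site by the versioned model config.
"""

from __future__ import annotations

import numpy as np

from .nn import Module, Conv, MaxPool, concat, chunk
from .reparam import DilatedReparamBlock

__all__ = ["Conv", "Bottleneck", "C2f", "SPPF", "DRBNBottleneck", "DRBNCSP", "DRModule"]


def _rng(rng):
    return rng if rng is not None else np.random.default_rng(0)


class Bottleneck(Module):
    """Standard two-conv bottleneck with optional residual."""

    def __init__(self, c1, c2, shortcut=True, e=0.5, k=(3, 3), rng=None):
        super().__init__()
        rng = _rng(rng)
        c_ = int(c2 * e)
        self.cv1 = Conv(c1, c_, k[0], rng=rng)
        self.cv2 = Conv(c_, c2, k[1], rng=rng)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C2f(Module):
    """Cross-stage-partial block with two convs (YOLOv8 baseline)."""

    def __init__(self, c1, c2, n=1, shortcut=False, e=0.5, rng=None):
        super().__init__()
        rng = _rng(rng)
        self.c = int(c2 * e)
        if (2 * self.c) % 2:
            raise ValueError("hidden channels must be even")
        self.cv1 = Conv(c1, 2 * self.c, 1, rng=rng)
        self.cv2 = Conv((2 + n) * self.c, c2, 1, rng=rng)
        self.m = [Bottleneck(self.c, self.c, shortcut, e=1.0, rng=rng) for _ in range(n)]

    def forward(self, x):
        y = chunk(self.cv1(x), 2, axis=1)
        for m in self.m:
            y.append(m(y[-1]))
        return self.cv2(concat(y, axis=1))


class SPPF(Module):
    """Spatial pyramid pooling (fast): three chained 5x5 max-pools."""

    def __init__(self, c1, c2, k=5, rng=None):
        super().__init__()
        rng = _rng(rng)
        c_ = c1 // 2
        self.cv1 = Conv(c1, c_, 1, rng=rng)
        self.cv2 = Conv(4 * c_, c2, 1, rng=rng)
        self.pool = MaxPool(k, 1)

    def forward(self, x):
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(self.pool(y[-1]))
        return self.cv2(concat(y, axis=1))


class DRBNBottleneck(Module):
    """Residual bottleneck: dense 3x3 conv then the dilated-reparam block."""

    def __init__(self, c1, c2, shortcut=True, rng=None):
        super().__init__()
        rng = _rng(rng)
        if shortcut and c1 != c2:
            raise ValueError("residual requires matching channels")
        self.cv1 = Conv(c1, c2, 3, rng=rng)
        self.drb = DilatedReparamBlock(c2, k=9, rng=rng)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.drb(self.cv1(x)).silu()
        return x + y if self.add else y


class DRBNCSP(Module):
    """CSP stage with DRBNBottlenecks (GELAN-style RepNCSP analogue)."""

    def __init__(self, c1, c2, n=1, e=0.5, rng=None):
        super().__init__()
        rng = _rng(rng)
        c_ = int(c2 * e)
        self.cv1 = Conv(c1, c_, 1, rng=rng)
        self.cv2 = Conv(c1, c_, 1, rng=rng)
        self.cv3 = Conv(2 * c_, c2, 1, rng=rng)
        self.m = [DRBNBottleneck(c_, c_, True, rng=rng) for _ in range(n)]

    def forward(self, x):
        a = self.cv1(x)
        for m in self.m:
            a = m(a)
        return self.cv3(concat([a, self.cv2(x)], axis=1))


class DRModule(Module):
    """Dilated-reparam feature-enhancement module (drop-in for C2f).

    ``c3`` must be even: the in-conv output is chunked into two halves.
    Stage widths: DRBNCSP maps to ``c4``; the 3x3 stage conv maps to ``c5``.
    """

    def __init__(self, c1, c2, c3, c4, c5=None, n=1, rng=None):
        super().__init__()
        rng = _rng(rng)
        if c3 % 2:
            raise ValueError(f"c3 must be even, got {c3}")
        c5 = c4 if c5 is None else c5
        self.c3 = c3
        self.cv1 = Conv(c1, c3, 1, rng=rng)
        self.csp1 = DRBNCSP(c3 // 2, c4, n, rng=rng)
        self.conv1 = Conv(c4, c5, 3, rng=rng)
        self.csp2 = DRBNCSP(c5, c4, n, rng=rng)
        self.conv2 = Conv(c4, c5, 3, rng=rng)
        self.cv4 = Conv(c3 + 2 * c5, c2, 1, rng=rng)

    def forward(self, x):
        y = chunk(self.cv1(x), 2, axis=1)
        y.append(self.conv1(self.csp1(y[-1])))
        y.append(self.conv2(self.csp2(y[-1])))
        return self.cv4(concat(y, axis=1))

    def merge_reparam(self):
        for m in self.modules():
            if isinstance(m, DilatedReparamBlock) and m.merged is None:
                m.merge()
        return self
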