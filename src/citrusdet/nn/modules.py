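"""Layer modules: parameter containers with forward passes on ``Tensor``.

Convention mirrors compact detector implementations: ``Conv`` is
conv + batch norm + SiLU with autopad, ``fuse()`` folds the batch norm
into an equivalent conv-with-bias for deployment/profiling.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d, max_pool2d

__all__ = ["Module", "Param", "Conv", "Conv2d", "BatchNorm2d", "autopad", "kaiming_init"]


def autopad(k: int, d: int = 1) -> int:
    """'same' padding for odd kernels (dilation-aware)."""
    ke = (k - 1) * d + 1
    return ke // 2


class Param(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)
        self.requires_grad = True  # Params stay trainable even under no_grad construction


class Module:
    def __init__(self):
        self._training = True

    # -- containers -------------------------------------------------------
    @staticmethod
    def _children(value):
        """Yield (suffix, item) for Modules/Params in arbitrarily nested lists."""
        if isinstance(value, (Module, Param)):
            yield "", value
        elif isinstance(value, (list, tuple)):
            for i, v in enumerate(value):
                for suffix, item in Module._children(v):
                    yield f".{i}{suffix}", item

    def modules(self):
        yield self
        for v in vars(self).values():
            for _, item in self._children(v):
                if isinstance(item, Module):
                    yield from item.modules()

    def named_parameters(self, prefix=""):
        for name, v in vars(self).items():
            for suffix, item in self._children(v):
                if isinstance(item, Param):
                    yield f"{prefix}{name}{suffix}", item
                else:
                    yield from item.named_parameters(f"{prefix}{name}{suffix}.")

    def parameters(self):
        seen = set()
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                yield p

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode=True):
        for m in self.modules():
            m._training = mode
        return self

    def eval(self):
        return self.train(False)

    @property
    def training(self):
        return self._training

    def num_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *a, **k):
        return self.forward(*a, **k)


def kaiming_init(rng: np.random.Generator, co, ci, kh, kw):
    fan_in = ci * kh * kw
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal((co, ci, kh, kw)) * std).astype(np.float32)


class Conv2d(Module):
    """Bare convolution, optional bias."""

    def __init__(self, c1, c2, k=1, s=1, p=None, g=1, d=1, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.c1, self.c2, self.k, self.s, self.g, self.d = c1, c2, k, s, g, d
        self.p = autopad(k, d) if p is None else p
        self.weight = Param(kaiming_init(rng, c2, c1 // g, k, k))
        self.bias = Param(np.zeros(c2, dtype=np.float32)) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.s, padding=self.p,
                      dilation=self.d, groups=self.g)


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-3, momentum=0.03):
        super().__init__()
        self.c, self.eps, self.momentum = c, eps, momentum
        self.gamma = Param(np.ones(c, dtype=np.float32))
        self.beta = Param(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x):
        if self.training:
            B, C, H, W = x.shape
            # full backward through batch statistics (keeps gradients normalized)
            xt = x.transpose(1, 0, 2, 3).reshape(C, B * H * W)
            mu = xt.mean(axis=1, keepdims=True)
            xc = xt - mu
            var = (xc * xc).mean(axis=1, keepdims=True)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var.data.ravel()
            xn = xc / (var + self.eps).sqrt()
            y = xn * self.gamma.reshape(C, 1) + self.beta.reshape(C, 1)
            return y.reshape(C, B, H, W).transpose(1, 0, 2, 3)
        else:
            # compute in float64 so eval-mode BN agrees with fused algebra to ~1e-13
            scale = (1.0 / np.sqrt(self.running_var.astype(np.float64) + self.eps)).reshape(1, -1, 1, 1)
            shift = (-self.running_mean.astype(np.float64)).reshape(1, -1, 1, 1)
            xn = (x + Tensor(shift.astype(x.data.dtype))) * Tensor(scale.astype(x.data.dtype))
        return xn * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class Conv(Module):
    """Conv2d + BatchNorm2d + SiLU (the detector's basic unit)."""

    def __init__(self, c1, c2, k=1, s=1, p=None, g=1, d=1, act=True, rng=None):
        super().__init__()
        self.conv = Conv2d(c1, c2, k, s, p, g, d, bias=False, rng=rng)
        self.bn = BatchNorm2d(c2)
        self.act = act

    def forward(self, x):
        y = self.bn(self.conv(x))
        return y.silu() if self.act else y

    def fuse(self) -> Conv2d:
        """Fold BN statistics into an equivalent conv-with-bias."""
        from ..reparam import fuse_conv_bn, Kernel, BNStats

        k = Kernel(self.conv.weight.data.astype(np.float64), None)
        bn = BNStats(self.bn.gamma.data.astype(np.float64), self.bn.beta.data.astype(np.float64),
                     self.bn.running_mean.astype(np.float64), self.bn.running_var.astype(np.float64),
                     self.bn.eps)
        fused = fuse_conv_bn(k, bn)
        m = Conv2d.__new__(Conv2d)
        Module.__init__(m)
        m.c1, m.c2, m.k, m.s, m.g, m.d, m.p = (self.conv.c1, self.conv.c2, self.conv.k,
                                               self.conv.s, self.conv.g, self.conv.d, self.conv.p)
        m.weight = Param(fused.weights.astype(np.float32))
        m.bias = Param(fused.bias.astype(np.float32))
        return m


class MaxPool(Module):
    def __init__(self, k=5, s=1, p=None):
        super().__init__()
        self.k, self.s = k, s
        self.p = k // 2 if p is None else p

    def forward(self, x):
        return max_pool2d(x, self.k, self.s, self.p)
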