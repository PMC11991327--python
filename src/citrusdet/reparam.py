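"""Structural re-parameterization of dilated convolutions.

A convolution with kernel size k and dilation r is algebraically identical
to a convolution with a sparse kernel of size (k-1)*r+1 and dilation 1:
inserting r-1 zeros between the original taps reproduces the same linear
map.  A block of parallel depthwise branches with different dilation rates
(each followed by batch norm) can therefore be collapsed, after BN fusion,
into a single dense large-kernel convolution by zero-padding every expanded
branch kernel to a common size and summing.  The default block merges a
9x9 branch with (k=5, r=1), (k=3, r=2) and (k=3, r=3) branches into one
9x9 kernel.

The algebra here operates on plain NumPy weight arrays; the trainable
``DilatedReparamBlock`` module at the bottom wraps it for the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor, Module, Param, Conv2d, BatchNorm2d, autopad, conv2d
from .nn.modules import kaiming_init

__all__ = [
    "Kernel", "BNStats", "DilatedBranch", "MergedKernel",
    "dilate_kernel", "fuse_conv_bn", "merge_branches", "verify_equivalence",
    "DilatedReparamBlock", "DEFAULT_BRANCHES",
]

#: (kernel size, dilation) of the parallel branches merged into the 9x9 kernel.
DEFAULT_BRANCHES = ((5, 1), (3, 2), (3, 3))


@dataclass
class Kernel:
    """Convolution weights (out, in, k, k) with optional per-output bias."""

    weights: np.ndarray
    bias: np.ndarray | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights)
        if self.weights.ndim != 4 or self.weights.shape[2] != self.weights.shape[3]:
            raise ValueError("kernel must be (out, in, k, k) with square spatial dims")
        if self.k % 2 == 0:
            raise ValueError(f"kernel size must be odd, got {self.k}")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("kernel weights must be finite")
        if self.bias is not None:
            self.bias = np.asarray(self.bias)
            if self.bias.shape != (self.out_channels,):
                raise ValueError("bias length must equal out_channels")

    @property
    def k(self) -> int:
        return self.weights.shape[2]

    @property
    def out_channels(self) -> int:
        return self.weights.shape[0]


@dataclass
class BNStats:
    """Batch-norm statistics: y = gamma * (x - mean) / sqrt(var + eps) + beta."""

    gamma: np.ndarray
    beta: np.ndarray
    running_mean: np.ndarray
    running_var: np.ndarray
    eps: float = 1e-3

    def __post_init__(self):
        for name in ("gamma", "beta", "running_mean", "running_var"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        n = self.gamma.shape[0]
        if any(getattr(self, f).shape != (n,) for f in ("beta", "running_mean", "running_var")):
            raise ValueError("BN vectors must share one length")
        if np.any(self.running_var < 0):
            raise ValueError("running_var must be non-negative")


@dataclass
class DilatedBranch:
    kernel: Kernel
    dilation: int
    bn: BNStats | None = None

    @property
    def effective_k(self) -> int:
        return (self.kernel.k - 1) * self.dilation + 1


@dataclass
class MergedKernel:
    kernel: Kernel

    @property
    def k(self) -> int:
        return self.kernel.k


def dilate_kernel(kernel: Kernel, r: int) -> Kernel:
    """Expand a kernel to its non-dilated sparse equivalent of size (k-1)*r+1.

    Convolving with (W, dilation=r) equals convolving with the expanded
    kernel at dilation 1; the inserted entries are exactly zero, so the
    weight sum is preserved.
    """
    if r < 1:
        raise ValueError(f"dilation must be >= 1, got {r}")
    k = kernel.k
    if r == 1:
        return Kernel(kernel.weights.copy(), None if kernel.bias is None else kernel.bias.copy())
    ke = (k - 1) * r + 1
    out = np.zeros(kernel.weights.shape[:2] + (ke, ke), dtype=kernel.weights.dtype)
    out[:, :, ::r, ::r] = kernel.weights
    return Kernel(out, None if kernel.bias is None else kernel.bias.copy())


def fuse_conv_bn(kernel: Kernel, bn: BNStats) -> Kernel:
    """Fold batch norm into the preceding conv: returns conv-with-bias.

    forward(fused, x) == bn(forward(kernel, x)) for every input.
    """
    if bn.gamma.shape[0] != kernel.out_channels:
        raise ValueError("BN channel count must match kernel out_channels")
    scale = bn.gamma / np.sqrt(bn.running_var + bn.eps)
    w = kernel.weights * scale[:, None, None, None]
    b0 = kernel.bias if kernel.bias is not None else 0.0
    b = (b0 - bn.running_mean) * scale + bn.beta
    return Kernel(w, b)


def _pad_center(w: np.ndarray, target_k: int) -> np.ndarray:
    k = w.shape[2]
    pad = (target_k - k) // 2
    if pad == 0:
        return w
    return np.pad(w, ((0, 0), (0, 0), (pad, pad), (pad, pad)))


def merge_branches(branches: list[DilatedBranch], target_k: int = 9) -> MergedKernel:
    """Collapse parallel dilated branches into one equivalent dense kernel.

    Each branch is expanded to its sparse non-dilated form, BN-fused if it
    carries statistics, zero-padded symmetrically to ``target_k`` and
    summed (odd sizes guarantee a common centre).  The merged forward
    equals the sum of the branch forwards for any input.
    """
    if not branches:
        raise ValueError("need at least one branch")
    shape = branches[0].kernel.weights.shape[:2]
    acc_w = np.zeros(shape + (target_k, target_k), dtype=np.float64)
    acc_b = np.zeros(shape[0], dtype=np.float64)
    for br in branches:
        if br.effective_k > target_k:
            raise ValueError(f"branch effective size {br.effective_k} exceeds target {target_k}")
        if br.kernel.weights.shape[:2] != shape:
            raise ValueError("branches must share in/out channels")
        expanded = dilate_kernel(br.kernel, br.dilation)
        if br.bn is not None:
            expanded = fuse_conv_bn(expanded, br.bn)
        acc_w += _pad_center(expanded.weights.astype(np.float64), target_k)
        if expanded.bias is not None:
            acc_b += expanded.bias
    return MergedKernel(Kernel(acc_w, acc_b))


def verify_equivalence(block, merged_fn, in_channels, n_trials=100, seed=0, size=16, dtype=np.float32):
    """Worst-case |block(x) - merged(x)| over seeded random inputs."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_trials):
        x = rng.standard_normal((1, in_channels, size, size)).astype(dtype)
        a = block(x)
        b = merged_fn(x)
        worst = max(worst, float(np.abs(np.asarray(a) - np.asarray(b)).max()))
    return worst


class DilatedReparamBlock(Module):
    """Depthwise large-kernel block trained as parallel dilated branches.

    Branches: a dense ``k x k`` depthwise conv plus ``DEFAULT_BRANCHES``
    dilated depthwise convs, each followed by BN.  ``merge()`` collapses
    the block into a single depthwise conv of size ``k`` with bias.
    """

    def __init__(self, dim: int, k: int = 9, branches=DEFAULT_BRANCHES, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.dim, self.k = dim, k
        self.branch_spec = tuple(branches)
        self.origin = Conv2d(dim, dim, k, 1, autopad(k), g=dim, bias=False, rng=rng)
        self.origin_bn = BatchNorm2d(dim)
        self.convs, self.bns = [], []
        for bk, br in self.branch_spec:
            if (bk - 1) * br + 1 > k:
                raise ValueError(f"branch ({bk},{br}) exceeds merge target {k}")
            self.convs.append(Conv2d(dim, dim, bk, 1, autopad(bk, br), g=dim, d=br, bias=False, rng=rng))
            self.bns.append(BatchNorm2d(dim))
        self.merged: MergedKernel | None = None

    def forward(self, x):
        if self.merged is not None:
            # merged weights kept in float64; computed at the input's precision
            w = Tensor(self.merged.kernel.weights.astype(x.data.dtype))
            b = Tensor(self.merged.kernel.bias.astype(x.data.dtype))
            return conv2d(x, w, b, stride=1, padding=autopad(self.k), groups=self.dim)
        y = self.origin_bn(self.origin(x))
        for conv, bn in zip(self.convs, self.bns):
            y = y + bn(conv(x))
        return y

    def _branches(self):
        def stats(bn):
            return BNStats(bn.gamma.data, bn.beta.data, bn.running_mean, bn.running_var, bn.eps)

        out = [DilatedBranch(Kernel(self.origin.weight.data.astype(np.float64)), 1, stats(self.origin_bn))]
        for (bk, br), conv, bn in zip(self.branch_spec, self.convs, self.bns):
            out.append(DilatedBranch(Kernel(conv.weight.data.astype(np.float64)), br, stats(bn)))
        return out

    def merge(self):
        """Re-parameterize into the single dense depthwise kernel (in place)."""
        self.merged = merge_branches(self._branches(), self.k)
        return self
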