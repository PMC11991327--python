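import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def finite_diff_grad(f, x0, eps=1e-6, n_check=40):
    """Central-difference gradient of scalar-valued f at up to n_check entries."""
    g = np.zeros_like(x0, dtype=np.float64)
    it = np.nditer(x0, flags=["multi_index"])
    for _ in range(min(x0.size, n_check)):
        i = it.multi_index
        xp = x0.copy()
        xp[i] += eps
        xm = x0.copy()
        xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
        it.iternext()
    return g


def direct_conv2d(x, w, b=None, stride=1, padding=0, dilation=1, groups=1):
    """Brute-force reference convolution: explicit loops over output positions."""
    B, C, H, W = x.shape
    Co, Cg, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    eh, ew = (kh - 1) * dilation + 1, (kw - 1) * dilation + 1
    Ho = (xp.shape[2] - eh) // stride + 1
    Wo = (xp.shape[3] - ew) // stride + 1
    out = np.zeros((B, Co, Ho, Wo), dtype=np.result_type(x, w))
    cpg = C // groups
    opg = Co // groups
    for bi in range(B):
        for co in range(Co):
            g = co // opg
            for i in range(Ho):
                for j in range(Wo):
                    acc = 0.0
                    for ci in range(Cg):
                        for u in range(kh):
                            for v in range(kw):
                                acc += (xp[bi, g * cpg + ci,
                                           i * stride + u * dilation,
                                           j * stride + v * dilation]
                                        * w[co, ci, u, v])
                    out[bi, co, i, j] = acc
    if b is not None:
        out += b.reshape(1, Co, 1, 1)
    return out
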