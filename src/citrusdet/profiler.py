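"""Per-layer parameter and FLOP accounting.

Conventions (fixed so totals land on the published style of accounting):

* Parameters are counted for the deployed model: batch norms folded into
  the preceding conv (weights + one bias per output channel) and every
  dilated-reparam block collapsed to its single merged kernel.  The
  head's frozen DFL projection (reg_max entries) is included.
* FLOPs = 2 x multiply-accumulates of the convolutions, counted from the
  conv weight tensors alone (biases, activations and elementwise adds are
  excluded; they are sub-0.1% terms at this scale).  Parameter counts are
  input-size invariant; FLOPs are reported at a stated square input size.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import BASE_LAYERS, DR_SITES, HEAD_CH, Model

__all__ = ["LayerProfile", "count_params", "count_flops", "profile_model",
           "compare_profiles", "profile_table"]


@dataclass
class LayerProfile:
    index: int
    name: str
    params: int
    flops: int  # at the stated input size; 2xMAC


# output stride of each layer index (input 640 -> spatial = (640/stride)^2)
_STRIDES = [2, 4, 4, 8, 8, 16, 16, 32, 32, 32, 16, 16, 16, 8, 8, 8, 16, 16, 16, 32, 32, 32, None]


def _conv(c1, c2, k, g=1):
    """(weights, params) of one fused conv."""
    w = k * k * (c1 // g) * c2
    return w, w + c2


def _convs(specs):
    w = p = 0
    for s in specs:
        a, b = _conv(*s)
        w += a
        p += b
    return w, p


def _c2f_specs(c1, c2, n):
    c = c2 // 2
    specs = [(c1, 2 * c, 1), ((2 + n) * c, c2, 1)]
    for _ in range(n):
        specs += [(c, c, 3), (c, c, 3)]
    return specs


def _dr_specs(c1, c2, c3, c4, c5, n):
    c_ = c4 // 2
    specs = [(c1, c3, 1)]
    for cin in (c3 // 2, c5):
        specs += [(cin, c_, 1), (cin, c_, 1)]
        for _ in range(n):
            specs += [(c_, c_, 3), (c_, c_, 9, c_)]   # bottleneck: dense 3x3 + merged dw 9x9
        specs += [(2 * c_, c4, 1), (c4, c5, 3)]
    specs += [(c3 + 2 * c5, c2, 1)]
    return specs


def _sppf_specs(c1, c2):
    c = c1 // 2
    return [(c1, c, 1), (4 * c, c2, 1)]


def _decoupled_head(nc, reg_max=16, ch=HEAD_CH):
    """Per-scale weight counts + total params of the baseline head."""
    c2 = max(16, ch[0] // 4, reg_max * 4)
    c3 = max(ch[0], min(nc, 100))
    per_scale_w, params = [], 0
    for c in ch:
        w, p = _convs([(c, c2, 3), (c2, c2, 3), (c2, 4 * reg_max, 1),
                       (c, c3, 3), (c3, c3, 3), (c3, nc, 1)])
        per_scale_w.append(w)
        params += p
    params += reg_max  # DFL projection
    return per_scale_w, params, reg_max


def _shared_head(nc, reg_max=16, ch=HEAD_CH):
    per_scale_w, params = [], 0
    for c in ch:
        pw = 9 * (c // 4) ** 2          # partial conv (bias-free slice conv)
        fw = c * c                      # 1x1 channel fusion
        rw = c * 4 * reg_max
        cw = c * nc
        per_scale_w.append(pw + fw + rw + cw)
        params += pw + (fw + c) + (rw + 4 * reg_max) + (cw + nc)
    params += len(ch)                   # per-scale regression scale factors
    params += reg_max                   # DFL projection
    return per_scale_w, params, reg_max


def profile_model(variant_or_model, nc=6, input_size=640):
    """Full per-layer profile of a variant (or an assembled Model)."""
    if isinstance(variant_or_model, Model):
        variant, nc = variant_or_model.variant, variant_or_model.nc
    else:
        variant = variant_or_model
        from .model import VARIANTS

        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    use_dr = variant in ("v8n-D", "v8n-DE")
    use_shared = variant in ("v8n-E", "v8n-DE")
    if input_size % 32:
        raise ValueError("input size must be a multiple of 32")
    rows = []
    for i, (frm, block, args) in enumerate(BASE_LAYERS):
        if block == "Conv":
            c1, c2, k, s = args
            specs, name = [(c1, c2, k)], "Conv"
        elif block == "C2f" and use_dr:
            specs = _dr_specs(args[0], args[1], *DR_SITES[i])
            name = "DR"
        elif block == "C2f":
            specs, name = _c2f_specs(args[0], args[1], args[2]), "C2f"
        elif block == "SPPF":
            specs, name = _sppf_specs(*args), "SPPF"
        elif block == "Detect":
            if use_shared:
                per_w, params, reg_max = _shared_head(nc)
                name = "DetectShared"
            else:
                per_w, params, reg_max = _decoupled_head(nc)
                name = "Detect"
            mac = 0
            for w, stride in zip(per_w, (8, 16, 32)):
                mac += w * (input_size // stride) ** 2
            mac += reg_max * 4 * sum((input_size // s) ** 2 for s in (8, 16, 32))  # DFL decode
            rows.append(LayerProfile(i, name, params, 2 * mac))
            continue
        else:
            rows.append(LayerProfile(i, block, 0, 0))
            continue
        w, p = _convs(specs)
        spatial = (input_size // _STRIDES[i]) ** 2
        rows.append(LayerProfile(i, name, p, 2 * w * spatial))
    return rows


def count_params(variant_or_model, nc=6):
    """Per-layer parameter profile and exact total."""
    rows = profile_model(variant_or_model, nc=nc)
    return rows, sum(r.params for r in rows)


def count_flops(variant_or_model, nc=6, input_size=640):
    """Per-layer 2xMAC FLOP profile at ``input_size`` and total."""
    rows = profile_model(variant_or_model, nc=nc, input_size=input_size)
    return rows, sum(r.flops for r in rows)


def compare_profiles(rows_a, rows_b):
    """Per-layer and total reduction percentages (a -> b), 2 decimals."""
    if len(rows_a) != len(rows_b) or any(x.index != y.index for x, y in zip(rows_a, rows_b)):
        raise ValueError("profiles have mismatched layer indexing")

    def red(a, b):
        return round((a - b) / a * 100, 2) if a else 0.0

    table = [
        {"index": x.index, "name_a": x.name, "name_b": y.name,
         "params_a": x.params, "params_b": y.params, "params_red": red(x.params, y.params),
         "flops_a": x.flops, "flops_b": y.flops, "flops_red": red(x.flops, y.flops)}
        for x, y in zip(rows_a, rows_b)
    ]
    pa, pb = sum(x.params for x in rows_a), sum(y.params for y in rows_b)
    fa, fb = sum(x.flops for x in rows_a), sum(y.flops for y in rows_b)
    total = {"params_a": pa, "params_b": pb, "params_red": red(pa, pb),
             "flops_a": fa, "flops_b": fb, "flops_red": red(fa, fb)}
    return table, total


def profile_table(variant, nc=6, input_size=640) -> str:
    """Human/CSV-friendly profile listing."""
    rows = profile_model(variant, nc=nc, input_size=input_size)
    lines = ["index,block,params,flops"]
    for r in rows:
        lines.append(f"{r.index},{r.name},{r.params},{r.flops}")
    lines.append(f"total,,{sum(r.params for r in rows)},{sum(r.flops for r in rows)}")
    return "\n".join(lines)
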