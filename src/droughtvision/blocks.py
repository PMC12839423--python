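"""Bio-inspired feature-map blocks: multi-scale linear attention and CMUNeXt.

MSLA (multi-scale linear attention) mirrors the primate visual pathway's
"multi-scale parallelism — global modulation — long-range integration":
the channel dimension is split into four equal branches, each filtered by a
residual depthwise convolution at a different kernel scale (3/5/7/9) with a
ReLU, flattened to a token sequence and passed through *linear* attention —
row-softmax on the queries, column-softmax on the keys, and the associative
regrouping ``phi_q(Q) (phi_k(K)^T V)`` so no N x N attention matrix is ever
materialized. Branch outputs are rescaled by learnable scalars and fused by
a 1 x 1 convolution, preserving the input shape.

The CMUNeXt block emulates retinal wide-field lateral inhibition followed by
cortical selective convergence: a residual large-kernel depthwise
convolution integrates long-range spatial context per channel, then two
pointwise (1 x 1) convolutions expand the channel space (C -> E) and project
back (E -> C); each of the three stages is followed by GELU and batch
normalization.
"""

from __future__ import annotations

import numpy as np

from .nn import core as ag
from .nn import layers as nl
from .nn.core import Tensor

__all__ = [
    "MSLA_KERNELS",
    "msla_branch",
    "linear_attention",
    "MSLABranch",
    "MSLA",
    "CMUNeXtBlock",
    "count_parameters",
]

MSLA_KERNELS = (3, 5, 7, 9)


# ---------------------------------------------------------------------------
# functional pieces (explicit weights — convenient for oracle tests)
# ---------------------------------------------------------------------------


def msla_branch(x: Tensor, weight: Tensor) -> Tensor:
    """One branch transform: ``ReLU(dwconv_k(x) + x)``, same padding.

    ``weight`` has shape (C, 1, k, k) with odd k; depthwise, stride 1.
    """
    x, weight = ag.as_tensor(x), ag.as_tensor(weight)
    c, _, k, _ = weight.data.shape
    if k % 2 == 0:
        raise ValueError(f"kernel {k} must be odd for same padding")
    if x.data.shape[1] != c:
        raise ValueError(f"channel mismatch: input {x.data.shape[1]}, weight {c}")
    return ag.relu(ag.conv2d(x, weight, stride=1, padding=k // 2, groups=c) + x)


def linear_attention(x: Tensor, w_q: Tensor, w_k: Tensor, w_v: Tensor,
                     w_o: Tensor | None = None, heads: int = 1) -> Tensor:
    """Linear (kernelized-softmax) attention over a token sequence.

    ``x`` is (..., N, d). Per head: ``O = phi_q(Q) @ (phi_k(K)^T @ V)`` where
    ``phi_q`` is a softmax over each query row (feature axis) and ``phi_k``
    a softmax over each key column (token axis). The d x d key/value
    aggregate replaces the N x N attention matrix. Heads are concatenated
    and linearly mapped by ``w_o`` (identity if omitted).
    """
    x = ag.as_tensor(x)
    d = x.data.shape[-1]
    if d % heads:
        raise ValueError(f"token dim {d} not divisible by {heads} heads")
    dh = d // heads
    q = x @ ag.as_tensor(w_q)
    k = x @ ag.as_tensor(w_k)
    v = x @ ag.as_tensor(w_v)

    def split_heads(t: Tensor) -> Tensor:
        lead = t.data.shape[:-2]
        n = t.data.shape[-2]
        t = t.reshape(lead + (n, heads, dh))
        order = tuple(range(len(lead))) + (len(lead) + 1, len(lead), len(lead) + 2)
        return t.transpose(order)  # (..., heads, N, dh)

    qh, kh, vh = split_heads(q), split_heads(k), split_heads(v)
    phi_q = ag.softmax(qh, axis=-1)   # each query row sums to 1
    phi_k = ag.softmax(kh, axis=-2)   # each key column sums to 1
    kt = phi_k.transpose(tuple(range(phi_k.ndim - 2)) + (phi_k.ndim - 1, phi_k.ndim - 2))
    out = phi_q @ (kt @ vh)           # (..., heads, N, dh); O(N d^2), not O(N^2 d)
    lead = out.data.shape[:-3]
    n = out.data.shape[-2]
    order = tuple(range(len(lead))) + (len(lead) + 1, len(lead), len(lead) + 2)
    out = out.transpose(order).reshape(lead + (n, d))
    if w_o is not None:
        out = out @ ag.as_tensor(w_o)
    return out


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


class MSLABranch(nl.Module):
    def __init__(self, c: int, kernel: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(rng.normal(0, np.sqrt(2.0 / (kernel * kernel)),
                                        (c, 1, kernel, kernel)), requires_grad=True)
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        return msla_branch(x, self.weight)


class MSLA(nl.Module):
    """Multi-scale linear attention over a (B, C, N, N) feature map.

    Requires C divisible by 4. ``heads`` applies per branch (default 1, head
    dim C/4). Branch fusion weights ``w_i`` start at 1; the fusion 1 x 1
    convolution carries a bias so the zero-weight degenerate case is exact.
    """

    def __init__(self, c: int, heads: int = 1, rng: np.random.Generator | None = None):
        super().__init__()
        if c < 4 or c % 4:
            raise ValueError(f"MSLA needs C >= 4 with C % 4 == 0, got {c}")
        rng = rng or np.random.default_rng(0)
        cb = c // 4
        if cb % heads:
            raise ValueError(f"branch dim {cb} not divisible by {heads} heads")
        self.c, self.heads = c, heads
        self.branches = [MSLABranch(cb, k, rng) for k in MSLA_KERNELS]
        scale = 1.0 / np.sqrt(cb)
        self.w_q = [Tensor(rng.normal(0, scale, (cb, cb)), requires_grad=True)
                    for _ in MSLA_KERNELS]
        self.w_k = [Tensor(rng.normal(0, scale, (cb, cb)), requires_grad=True)
                    for _ in MSLA_KERNELS]
        self.w_v = [Tensor(rng.normal(0, scale, (cb, cb)), requires_grad=True)
                    for _ in MSLA_KERNELS]
        self.w_o = [Tensor(rng.normal(0, scale, (cb, cb)), requires_grad=True)
                    for _ in MSLA_KERNELS]
        self.fusion_scale = Tensor(np.ones(4), requires_grad=True)  # w_1..w_4
        self.fusion = nl.Conv2d(c, c, 1, rng=rng)
        self.fusion_bias = Tensor(np.zeros(c), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        x = ag.as_tensor(x)
        B, C, H, W = x.data.shape
        if C != self.c:
            raise ValueError(f"expected {self.c} channels, got {C}")
        cb = C // 4
        outs = []
        for i in range(4):
            xi = x[:, i * cb:(i + 1) * cb]
            xb = self.branches[i](xi)
            tokens = xb.reshape(B, cb, H * W).transpose(0, 2, 1)  # (B, N^2, cb)
            o = linear_attention(tokens, self.w_q[i], self.w_k[i], self.w_v[i],
                                 self.w_o[i], heads=self.heads)
            o = o.transpose(0, 2, 1).reshape(B, cb, H, W)
            outs.append(o * self.fusion_scale[i])
        fused = ag.concatenate(outs, axis=1)
        return self.fusion(fused) + self.fusion_bias.reshape(1, C, 1, 1)


class CMUNeXtBlock(nl.Module):
    """Residual large-kernel depthwise stage + pointwise expand/reduce.

    ``f' = BN(GELU(dw_k(f) + f))``; ``f'' = BN(GELU(pw_{C->E}(f')))``;
    ``f_out = BN(GELU(pw_{E->C}(f'')))``. Defaults: kernel 7, expansion
    E = 4C, ``depth`` repeats of the whole block.
    """

    def __init__(self, c: int, depth: int = 1, kernel: int = 7,
                 expansion: int = 4, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if kernel % 2 == 0:
            raise ValueError("depthwise kernel must be odd")
        e = expansion * c
        if e < c:
            raise ValueError("expanded width must be >= C")
        self.depth = depth
        self.dw, self.bn1, self.pw1, self.bn2, self.pw2, self.bn3 = \
            [], [], [], [], [], []
        for _ in range(depth):
            self.dw.append(nl.Conv2d(c, c, kernel, groups=c, rng=rng))
            self.bn1.append(nl.BatchNorm2d(c))
            self.pw1.append(nl.Conv2d(c, e, 1, rng=rng))
            self.bn2.append(nl.BatchNorm2d(e))
            self.pw2.append(nl.Conv2d(e, c, 1, rng=rng))
            self.bn3.append(nl.BatchNorm2d(c))

    def forward(self, f: Tensor) -> Tensor:
        for i in range(self.depth):
            f1 = self.bn1[i](ag.gelu(self.dw[i](f) + f))
            f2 = self.bn2[i](ag.gelu(self.pw1[i](f1)))
            f = self.bn3[i](ag.gelu(self.pw2[i](f2)))
        return f


def count_parameters(block) -> int:
    """Trainable-scalar count of a block.

    Accepts either a built module or a ``(module_name, args)`` spec in the
    architecture-table argument vocabulary (e.g. ``("Conv", [3, 16, 3, 2])``),
    which is instantiated through the model registry and counted. Batch-norm
    running statistics are excluded; conv stages carry no bias.
    """
    if isinstance(block, nl.Module):
        return block.count_parameters()
    from .model import build_module  # lazy: model depends on blocks

    name, args = block
    return build_module(name, list(args)).count_parameters()
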