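"""MSLA / CMUNeXt blocks against independent straight-line oracles."""

import numpy as np
import pytest

from droughtvision import blocks as B
from droughtvision.nn import core as ag


def naive_depthwise(x, w):
    """Direct sliding-window depthwise convolution (same padding)."""
    _, c, H, W = x.shape
    k = w.shape[-1]
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    out = np.zeros_like(x)
    for ci in range(c):
        for i in range(H):
            for j in range(W):
                out[:, ci, i, j] = (xp[:, ci, i:i + k, j:j + k] * w[ci, 0]).sum(
                    axis=(1, 2))
    return out


def naive_softmax(a, axis):
    e = np.exp(a - a.max(axis=axis, keepdims=True))
    return e / (e.sum(axis=axis, keepdims=True) + 1e-12)


def naive_linear_attention(x, wq, wk, wv, wo, heads):
    """Materializes the N x N attention matrix explicitly, per batch/head."""
    d = x.shape[-1]
    dh = d // heads
    outs = []
    for b in range(x.shape[0]):
        per_head = []
        for h in range(heads):
            sl = slice(h * dh, (h + 1) * dh)
            Q, K, V = (x[b] @ wq)[:, sl], (x[b] @ wk)[:, sl], (x[b] @ wv)[:, sl]
            A = naive_softmax(Q, -1) @ naive_softmax(K, 0).T
            per_head.append(A @ V)
        outs.append(np.concatenate(per_head, axis=-1) @ wo)
    return np.stack(outs)


class TestMSLABranch:
    def test_zero_weights_reduce_to_relu(self, rng):
        x = rng.normal(size=(1, 8, 5, 5))
        out = B.msla_branch(ag.Tensor(x), ag.Tensor(np.zeros((8, 1, 3, 3))))
        assert np.allclose(out.data, np.maximum(x, 0))

    def test_shape_contract(self, rng):
        x = rng.normal(size=(1, 8, 16, 16))
        w = rng.normal(size=(8, 1, 5, 5))
        assert B.msla_branch(ag.Tensor(x), ag.Tensor(w)).data.shape == (1, 8, 16, 16)

    @pytest.mark.parametrize("k", [3, 5, 7, 9])
    def test_matches_direct_convolution_oracle(self, rng, k):
        x = rng.normal(size=(2, 4, 10, 10))
        w = rng.normal(size=(4, 1, k, k))
        got = B.msla_branch(ag.Tensor(x), ag.Tensor(w)).data
        want = np.maximum(naive_depthwise(x, w) + x, 0)
        assert np.allclose(got, want, atol=1e-5)

    def test_rejects_even_kernel_and_channel_mismatch(self, rng):
        with pytest.raises(ValueError):
            B.msla_branch(ag.Tensor(np.zeros((1, 4, 4, 4))),
                          ag.Tensor(np.zeros((4, 1, 4, 4))))
        with pytest.raises(ValueError):
            B.msla_branch(ag.Tensor(np.zeros((1, 4, 4, 4))),
                          ag.Tensor(np.zeros((8, 1, 3, 3))))


class TestLinearAttention:
    def test_softmax_normalization(self, rng):
        q = rng.normal(size=(6, 5))
        assert np.allclose(naive_softmax(q, -1).sum(axis=-1), 1)
        assert np.allclose(naive_softmax(q, 0).sum(axis=0), 1)

    def test_single_token_degenerate(self, rng):
        x = rng.normal(size=(1, 1, 4))
        wq, wk, wv = (rng.normal(size=(4, 4)) for _ in range(3))
        out = B.linear_attention(ag.Tensor(x), wq, wk, wv, heads=1).data
        # with one token both softmaxes are trivial: output = value projection
        assert np.allclose(out, x @ wv, atol=1e-9)

    @pytest.mark.parametrize("n, d, heads", [(4, 4, 1), (16, 8, 2), (32, 16, 4)])
    def test_associativity_oracle(self, rng, n, d, heads):
        """phi_q(Q) (phi_k(K)^T V) equals the naive (phi_q phi_k^T) V order."""
        x = rng.normal(size=(2, n, d))
        wq, wk, wv, wo = (rng.normal(size=(d, d)) for _ in range(4))
        got = B.linear_attention(ag.Tensor(x), wq, wk, wv, wo, heads=heads).data
        want = naive_linear_attention(x, wq, wk, wv, wo, heads)
        assert np.allclose(got, want, atol=1e-5)

    def test_output_rows_are_convex_combinations(self, rng):
        # each output row must lie inside the per-channel hull of phi_k(K)^T V
        x = rng.normal(size=(1, 12, 6))
        wq, wk, wv = (rng.normal(size=(6, 6)) for _ in range(3))
        out = B.linear_attention(ag.Tensor(x), wq, wk, wv, heads=1).data[0]
        kv = naive_softmax(x[0] @ wk, 0).T @ (x[0] @ wv)
        assert np.all(out <= kv.max(axis=0) + 1e-9)
        assert np.all(out >= kv.min(axis=0) - 1e-9)

    def test_head_divisibility_error(self, rng):
        x = rng.normal(size=(1, 4, 6))
        w = rng.normal(size=(6, 6))
        with pytest.raises(ValueError):
            B.linear_attention(ag.Tensor(x), w, w, w, heads=4)


class TestMSLA:
    def test_shape_preserved(self, rng):
        m = B.MSLA(32, rng=rng)
        x = rng.normal(size=(2, 32, 8, 8))
        assert m(ag.Tensor(x)).data.shape == (2, 32, 8, 8)

    def test_zero_fusion_weights_zero_output(self, rng):
        m = B.MSLA(8, rng=rng)
        m.fusion_scale.data[:] = 0.0
        m.fusion_bias.data[:] = 0.0
        x = rng.normal(size=(1, 8, 4, 4))
        assert np.allclose(m(ag.Tensor(x)).data, 0.0, atol=1e-12)

    def test_full_forward_matches_straightline_oracle(self, rng):
        """Independent re-composition: branch -> tokens -> attention -> fuse."""
        m = B.MSLA(8, rng=rng)
        x = rng.normal(size=(1, 8, 4, 4))
        got = m(ag.Tensor(x)).data

        cb = 2
        branch_outs = []
        for i in range(4):
            xi = x[:, i * cb:(i + 1) * cb]
            xb = np.maximum(naive_depthwise(xi, m.branches[i].weight.data) + xi, 0)
            tokens = xb.reshape(1, cb, 16).transpose(0, 2, 1)
            o = naive_linear_attention(tokens, m.w_q[i].data, m.w_k[i].data,
                                       m.w_v[i].data, m.w_o[i].data, heads=1)
            o = o.transpose(0, 2, 1).reshape(1, cb, 4, 4)
            branch_outs.append(o * m.fusion_scale.data[i])
        fused = np.concatenate(branch_outs, axis=1)
        w1x1 = m.fusion.weight.data  # (8, 8, 1, 1)
        want = np.einsum("bchw,oc->bohw", fused, w1x1[:, :, 0, 0])
        want = want + m.fusion_bias.data.reshape(1, 8, 1, 1)
        assert np.allclose(got, want, atol=1e-5)

    def test_rejects_bad_channel_count(self):
        with pytest.raises(ValueError):
            B.MSLA(6)

    def test_gradient_reaches_input_through_residuals(self, rng):
        m = B.MSLA(8, rng=rng)
        for br in m.branches:
            br.weight.data[:] = 0.0  # kill the convolution path
        x = ag.Tensor(rng.normal(size=(1, 8, 4, 4)), requires_grad=True)
        loss = (m(x) ** 2).sum()
        loss.backward()
        assert np.abs(x.grad).max() > 0


class TestCMUNeXt:
    def test_shape_preserved(self, rng):
        blk = B.CMUNeXtBlock(64, rng=rng)
        x = rng.normal(size=(1, 64, 8, 8))
        assert blk(ag.Tensor(x)).data.shape == (1, 64, 8, 8)

    def test_constant_input_gives_constant_interior(self, rng):
        # pointwise stages are spatially invariant; only the depthwise stage's
        # zero-padding border can deviate, so the interior must stay constant
        blk = B.CMUNeXtBlock(8, kernel=3, rng=rng).eval()
        x = np.full((1, 8, 8, 8), 0.7)
        out = blk(ag.Tensor(x)).data[:, :, 1:-1, 1:-1]
        spatial_var = out.var(axis=(2, 3))
        assert np.allclose(spatial_var, 0.0, atol=1e-18)

    def test_matches_staged_oracle(self, rng):
        blk = B.CMUNeXtBlock(8, kernel=3, expansion=2, rng=rng).eval()
        x = rng.normal(size=(1, 8, 4, 4))

        def gelu(z):
            from scipy.special import erf
            return 0.5 * z * (1 + erf(z / np.sqrt(2)))

        def bn_eval(z, bn):
            mu = bn.running_mean.reshape(1, -1, 1, 1)
            sd = np.sqrt(bn.running_var + bn.eps).reshape(1, -1, 1, 1)
            return ((z - mu) / sd) * bn.gamma.data.reshape(1, -1, 1, 1) \
                + bn.beta.data.reshape(1, -1, 1, 1)

        def pw(z, w):
            return np.einsum("bchw,oc->bohw", z, w[:, :, 0, 0])

        f1 = bn_eval(gelu(naive_depthwise(x, blk.dw[0].weight.data) + x), blk.bn1[0])
        f2 = bn_eval(gelu(pw(f1, blk.pw1[0].weight.data)), blk.bn2[0])
        want = bn_eval(gelu(pw(f2, blk.pw2[0].weight.data)), blk.bn3[0])
        got = blk(ag.Tensor(x)).data
        assert np.allclose(got, want, atol=1e-5)

    def test_expansion_must_not_shrink(self):
        with pytest.raises(ValueError):
            B.CMUNeXtBlock(8, expansion=0)


class TestCountParameters:
    @pytest.mark.parametrize(
        "spec, expected",
        [
            (("Conv", [3, 16, 3, 2]), 464),
            (("Conv", [16, 32, 3, 2, 1, 2]), 2368),
            (("Conv", [64, 64, 3, 2, 1, 4]), 9344),
            (("Conv", [128, 64, 1, 1]), 8320),
            (("Conv", [64, 64, 3, 2]), 36992),
            (("Conv", [128, 128, 3, 2]), 147712),
            (("DSConv", [128, 128, 3, 2]), 17792),
            (("DSConv", [128, 256, 3, 2]), 34432),
            (("DownsampleConv", [128]), 33280),
            (("FullPAD_Tunnel", []), 1),
            (("Upsample", [None, 2, "nearest"]), 0),
            (("Concat", [1]), 0),
        ],
    )
    def test_reference_rows(self, spec, expected):
        assert B.count_parameters(spec) == expected

    def test_counts_built_module(self, rng):
        m = B.MSLA(8, rng=rng)
        manual = sum(p.data.size for p in m.parameters())
        assert B.count_parameters(m) == manual
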