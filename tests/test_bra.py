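"""Bi-level routing attention: oracles and invariants."""

import numpy as np
import pytest

from srnetyolo.bra import (AttentionConfig, BiFormerBlock, ProjectionWeights,
                           bra_forward, gather_kv, project_qkv, region_merge,
                           region_partition, region_routing, token_attention)
from srnetyolo.nn import Tensor, functional as F


def dense_attention_oracle(x, Wq, Wk, Wv, num_heads, lce_weight=None, lce_kernel=5):
    """O(n^2) dense multi-head attention over all spatial tokens + LCE."""
    B, C, H, W = x.shape
    tokens = x.transpose(0, 2, 3, 1).reshape(B, H * W, C)
    q, k, v = tokens @ Wq, tokens @ Wk, tokens @ Wv
    hd = C // num_heads
    out = np.zeros_like(tokens)
    for b in range(B):
        for h in range(num_heads):
            qs = q[b, :, h * hd : (h + 1) * hd]
            ks = k[b, :, h * hd : (h + 1) * hd]
            vs = v[b, :, h * hd : (h + 1) * hd]
            logits = qs @ ks.T / np.sqrt(hd)
            e = np.exp(logits - logits.max(axis=1, keepdims=True))
            a = e / e.sum(axis=1, keepdims=True)
            out[b, :, h * hd : (h + 1) * hd] = a @ vs
    out = out.reshape(B, H, W, C).transpose(0, 3, 1, 2)
    if lce_weight is not None:
        v_map = v.reshape(B, H, W, C).transpose(0, 3, 1, 2)
        out = out + F.conv2d(Tensor(v_map), Tensor(lce_weight), None, 1,
                             lce_kernel // 2, groups=C).data
    return out


class TestRegionPartition:
    def test_round_trip_identity(self, rng):
        for S in (1, 2, 4):
            x = Tensor(rng.standard_normal((2, 3, 8, 8)))
            xr = region_partition(x, S)
            back = region_merge(xr, S, 8, 8)
            np.testing.assert_array_equal(back.data, x.data)

    def test_region_shapes(self, rng):
        x = Tensor(rng.standard_normal((1, 5, 8, 8)))
        xr = region_partition(x, 2)
        assert xr.shape == (1, 4, 16, 5)

    def test_token_placement_brute_force(self, rng):
        """Token (r, c) of a 6x6 map with S=3 lands in region 3*(r//2)+(c//2)."""
        x = rng.standard_normal((1, 3, 6, 6))
        xr = region_partition(Tensor(x), 3).data
        for r in range(6):
            for c in range(6):
                region = (r // 2) * 3 + (c // 2)
                token = (r % 2) * 2 + (c % 2)
                np.testing.assert_array_equal(xr[0, region, token], x[0, :, r, c])

    def test_non_divisible_raises(self, rng):
        with pytest.raises(ValueError, match="divide"):
            region_partition(Tensor(rng.standard_normal((1, 2, 6, 6))), 4)


class TestProjectQKV:
    def test_identity_weights(self, rng):
        xr = Tensor(rng.standard_normal((1, 4, 4, 8)))
        q, k, v = project_qkv(xr, ProjectionWeights.identity(8))
        for t in (q, k, v):
            np.testing.assert_allclose(t.data, xr.data, rtol=1e-6)

    def test_hand_arithmetic(self):
        xr = Tensor(np.array([1.0, 2.0]).reshape(1, 1, 1, 2))
        w = ProjectionWeights(
            Wq=Tensor(np.array([[1.0, 0.0], [0.0, 2.0]])),
            Wk=Tensor(np.eye(2)), Wv=Tensor(np.eye(2)))
        q, _, _ = project_qkv(xr, w)
        np.testing.assert_allclose(q.data.ravel(), [1.0, 4.0])

    def test_matches_token_loop(self, rng):
        xr = rng.standard_normal((2, 4, 4, 8))
        w = ProjectionWeights.random(8, rng)
        q, k, v = project_qkv(Tensor(xr), w)
        for t, W in ((q, w.Wq), (k, w.Wk), (v, w.Wv)):
            expect = np.empty_like(xr)
            for b in range(2):
                for r in range(4):
                    for tk in range(4):
                        expect[b, r, tk] = xr[b, r, tk] @ W.data
            np.testing.assert_allclose(t.data, expect, rtol=1e-5)

    def test_channel_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="shape"):
            project_qkv(Tensor(rng.standard_normal((1, 4, 4, 8))),
                        ProjectionWeights.identity(4))


class TestRegionRouting:
    def test_full_routing_is_permutation(self, rng):
        Q = Tensor(rng.standard_normal((1, 4, 3, 6)))
        K = Tensor(rng.standard_normal((1, 4, 3, 6)))
        tables = region_routing(Q, K, k=4)
        for row in tables.Ir[0]:
            assert sorted(row.tolist()) == [0, 1, 2, 3]

    def test_argmax_per_row(self):
        # construct Q, K whose region means produce Ar = [[3, 1], [0, 5]]
        Qr = np.array([[1.0, 0.0], [0.0, 1.0]])
        Kr = np.array([[3.0, 0.0], [1.0, 5.0]])  # Qr @ Kr.T == [[3, 1], [0, 5]]
        Q = Tensor(Qr[None, :, None, :])
        K = Tensor(Kr[None, :, None, :])
        tables = region_routing(Q, K, k=1)
        np.testing.assert_array_equal(tables.Ar[0], [[3.0, 1.0], [0.0, 5.0]])
        np.testing.assert_array_equal(tables.Ir[0], [[0], [1]])

    def test_matches_sort_oracle(self, rng):
        for trial in range(100):
            r = np.random.default_rng(trial)
            S2 = int(r.integers(2, 10))
            k = int(r.integers(1, S2 + 1))
            Q = Tensor(r.standard_normal((1, S2, 4, 6)))
            K = Tensor(r.standard_normal((1, S2, 4, 6)))
            tables = region_routing(Q, K, k)
            Ar = Q.data.mean(axis=2) @ K.data.mean(axis=2).transpose(0, 2, 1)
            for i in range(S2):
                full = sorted(range(S2), key=lambda j: (-Ar[0, i, j], j))
                assert tables.Ir[0, i].tolist() == full[:k]

    def test_routing_monotonicity(self, rng):
        Q = Tensor(rng.standard_normal((1, 9, 4, 6)))
        K = Tensor(rng.standard_normal((1, 9, 4, 6)))
        for k1, k2 in [(1, 3), (3, 6), (6, 9)]:
            I1 = region_routing(Q, K, k1).Ir
            I2 = region_routing(Q, K, k2).Ir
            for i in range(9):
                assert set(I1[0, i]) <= set(I2[0, i])

    def test_bad_k_raises(self, rng):
        Q = Tensor(rng.standard_normal((1, 4, 2, 3)))
        with pytest.raises(ValueError):
            region_routing(Q, Q, 0)
        with pytest.raises(ValueError):
            region_routing(Q, Q, 5)


class TestGatherKV:
    def test_full_gather(self, rng):
        K = Tensor(rng.standard_normal((1, 2, 3, 4)))
        V = Tensor(rng.standard_normal((1, 2, 3, 4)))
        Ir = np.array([[[0, 1], [0, 1]]])
        Kg, _ = gather_kv(K, V, Ir)
        flat = K.data.reshape(1, 6, 4)
        for i in range(2):
            np.testing.assert_array_equal(Kg.data[0, i], flat[0])

    def test_swap_permutation(self, rng):
        K = Tensor(rng.standard_normal((1, 2, 3, 4)))
        V = Tensor(rng.standard_normal((1, 2, 3, 4)))
        Kg, Vg = gather_kv(K, V, np.array([[[1], [0]]]))
        np.testing.assert_array_equal(Kg.data[0, 0], K.data[0, 1])
        np.testing.assert_array_equal(Kg.data[0, 1], K.data[0, 0])
        np.testing.assert_array_equal(Vg.data[0, 0], V.data[0, 1])

    def test_matches_concatenation_loop(self, rng):
        K = Tensor(rng.standard_normal((2, 4, 3, 5)))
        V = Tensor(rng.standard_normal((2, 4, 3, 5)))
        Ir = np.stack([np.array([[2, 0], [1, 3], [0, 0], [3, 1]]),
                       np.array([[1, 1], [0, 2], [3, 0], [2, 3]])])
        Kg, Vg = gather_kv(K, V, Ir)
        for b in range(2):
            for i in range(4):
                expect = np.concatenate([K.data[b, j] for j in Ir[b, i]])
                np.testing.assert_array_equal(Kg.data[b, i], expect)

    def test_out_of_range_raises(self, rng):
        K = Tensor(rng.standard_normal((1, 2, 3, 4)))
        with pytest.raises(IndexError):
            gather_kv(K, K, np.array([[[2], [0]]]))


class TestTokenAttention:
    def test_constant_value_collapse(self, rng):
        """With every value token equal to c, softmax convexity gives c."""
        cfg = AttentionConfig(S=2, k=4, num_heads=2, lce_kernel=5)
        Q = Tensor(rng.standard_normal((1, 4, 4, 8)))
        Kg = Tensor(rng.standard_normal((1, 4, 16, 8)))
        c = rng.standard_normal(8)
        Vg = Tensor(np.broadcast_to(c, (1, 4, 16, 8)).copy())
        V = Tensor(np.broadcast_to(c, (1, 4, 4, 8)).copy())
        out = token_attention(Q, Kg, Vg, V, cfg, (4, 4), lce_weight=None)
        expect = np.broadcast_to(c.reshape(1, 8, 1, 1), (1, 8, 4, 4))
        np.testing.assert_allclose(out.data, expect, atol=1e-5)

    def test_softmax_degenerate_single_token(self, rng):
        cfg = AttentionConfig(S=2, k=1, num_heads=1, lce_kernel=3)
        # HW/S^2 = 1: a 2x2 map with S=2
        Q = Tensor(rng.standard_normal((1, 4, 1, 4)))
        Kg = Tensor(rng.standard_normal((1, 4, 1, 4)))
        Vg = Tensor(rng.standard_normal((1, 4, 1, 4)))
        V = Tensor(rng.standard_normal((1, 4, 1, 4)))
        lce = np.zeros((4, 1, 3, 3), dtype=np.float32)
        out = token_attention(Q, Kg, Vg, V, cfg, (2, 2), Tensor(lce))
        expect = region_merge(Vg, 2, 2, 2)
        np.testing.assert_allclose(out.data, expect.data, atol=1e-6)

    def test_head_mismatch_raises(self, rng):
        cfg = AttentionConfig(S=2, k=1, num_heads=3)
        Q = Tensor(rng.standard_normal((1, 4, 1, 4)))
        with pytest.raises(ValueError, match="num_heads"):
            token_attention(Q, Q, Q, Q, cfg, (2, 2))


class TestBraForward:
    def test_shape_preserved(self, rng):
        x = Tensor(rng.standard_normal((1, 16, 8, 8)))
        w = ProjectionWeights.random(16, rng)
        out = bra_forward(x, w, AttentionConfig(S=2, k=2, num_heads=4))
        assert out.shape == x.shape

    @pytest.mark.parametrize("seed", range(20))
    def test_dense_limit_matches_oracle(self, seed):
        """k = S^2 routes every region: BRA must equal dense attention + LCE."""
        r = np.random.default_rng(seed)
        x = r.standard_normal((1, 16, 8, 8)).astype(np.float32)
        w = ProjectionWeights.random(16, r)
        lce = (r.standard_normal((16, 1, 5, 5)) / 5).astype(np.float32)
        cfg = AttentionConfig(S=2, k=4, num_heads=2, lce_kernel=5)
        out = bra_forward(Tensor(x), w, cfg, Tensor(lce))
        expect = dense_attention_oracle(x, w.Wq.data, w.Wk.data, w.Wv.data,
                                        2, lce, 5)
        assert np.abs(out.data - expect).max() <= 1e-5

    def test_single_region_limit(self, rng):
        """S=1 forces self-routing; equals dense attention + LCE."""
        x = rng.standard_normal((1, 8, 4, 4)).astype(np.float32)
        w = ProjectionWeights.random(8, rng)
        lce = (rng.standard_normal((8, 1, 5, 5)) / 5).astype(np.float32)
        cfg = AttentionConfig(S=1, k=1, num_heads=2)
        out = bra_forward(Tensor(x), w, cfg, Tensor(lce))
        expect = dense_attention_oracle(x, w.Wq.data, w.Wk.data, w.Wv.data, 2, lce)
        assert np.abs(out.data - expect).max() <= 1e-5

    def test_region_permutation_equivariance(self, rng):
        """Permuting regions of the input permutes regions of the output (no LCE)."""
        cfg = AttentionConfig(S=2, k=4, num_heads=2)
        x = rng.standard_normal((1, 8, 4, 4)).astype(np.float32)
        w = ProjectionWeights.random(8, rng)
        out = bra_forward(Tensor(x), w, cfg)
        perm = [2, 0, 3, 1]
        xr = region_partition(Tensor(x), 2)
        xp = region_merge(xr[:, perm], 2, 4, 4)
        outp = bra_forward(xp, w, cfg)
        outr = region_partition(out, 2)
        outpr = region_partition(outp, 2)
        np.testing.assert_allclose(outpr.data, outr.data[:, perm], atol=1e-5)

    def test_attention_weights_sum_to_one(self, rng):
        q = Tensor(rng.standard_normal((1, 4, 2, 3, 5)))
        a = q.softmax(axis=-1)
        np.testing.assert_allclose(a.data.sum(axis=-1), 1.0, atol=1e-6)


class TestBiFormerBlock:
    def test_zero_residual_case(self, rng):
        blk = BiFormerBlock(8, AttentionConfig(S=2, k=2, num_heads=2), rng)
        x = Tensor(rng.standard_normal((1, 8, 4, 4)).astype(np.float32))
        # output projection of BRA and second MLP layer are zero-initialised
        out = blk(x)
        expect = x + blk.pos(x)
        np.testing.assert_allclose(out.data, expect.data, atol=1e-6)

    def test_shape_preserved(self, rng):
        blk = BiFormerBlock(32, AttentionConfig(S=4, k=4, num_heads=4), rng)
        x = Tensor(rng.standard_normal((1, 32, 16, 16)).astype(np.float32))
        assert blk(x).shape == x.shape

    def test_gradient_reaches_every_parameter(self, rng):
        blk = BiFormerBlock(8, AttentionConfig(S=2, k=2, num_heads=2), rng)
        x = Tensor(rng.standard_normal((2, 8, 4, 4)).astype(np.float32))
        target = rng.standard_normal((2, 8, 4, 4)).astype(np.float32)
        loss = ((blk(x) - Tensor(target)) ** 2).mean()
        loss.backward()
        for name, p in blk.named_parameters():
            assert p.grad is not None, name
            assert np.all(np.isfinite(p.grad)), name
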