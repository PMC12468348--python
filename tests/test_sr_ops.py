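import numpy as np
import pytest
from scipy.signal import correlate2d

from retinasr._tensor import Tensor
from retinasr.sr_ops import (BASE_OFFSETS, DeformableKernelParams,
                             NonLocalBlock, NonLocalConfig, OffsetPredictor,
                             PatchSequence, PatchTransformer, deformable_conv,
                             learn_offsets, nonlocal_block, patch_transformer,
                             patchify, pixel_shuffle, pixel_unshuffle,
                             pointwise_conv, unpatchify)


def _standard_conv_oracle(x, w):
    """Zero-padded 3x3 convolution of (C,H,W) with (F,C,9) tap weights."""
    F = w.shape[0]
    out = np.zeros((F,) + x.shape[1:])
    for f in range(F):
        for c in range(x.shape[0]):
            out[f] += correlate2d(x[c], w[f, c].reshape(3, 3),
                                  mode="same", boundary="fill")
    return out


class TestDeformableConv:
    def test_zero_offsets_equal_standard_conv_50_instances(self, rng64):
        for _ in range(50):
            C, F = int(rng64.integers(1, 4)), int(rng64.integers(1, 4))
            H, W = int(rng64.integers(3, 8)), int(rng64.integers(3, 8))
            x = rng64.standard_normal((C, H, W))
            w = rng64.standard_normal((F, C, 9))
            params = DeformableKernelParams(
                weights=w, offsets=np.zeros((18, H, W)),
                modulations=np.ones((9, H, W)))
            out = deformable_conv(x, params)
            assert np.abs(out - _standard_conv_oracle(x, w)).max() < 1e-10

    def test_column_shift_oracle(self, rng64):
        C, F, H, W = 2, 2, 7, 7
        x = rng64.standard_normal((C, H, W))
        w = rng64.standard_normal((F, C, 9))
        offs = np.tile(np.array([0.0, 1.0] * 9)[:, None, None], (1, H, W))
        out = deformable_conv(x, DeformableKernelParams(
            weights=w, offsets=offs, modulations=np.ones((9, H, W))))
        shifted = np.zeros_like(x)
        shifted[:, :, :-1] = x[:, :, 1:]
        ref = _standard_conv_oracle(shifted, w)
        # interior columns: both paddings out of play
        assert np.abs(out[:, :, 1:W - 2] - ref[:, :, 1:W - 2]).max() < 1e-10

    def test_half_offset_samples_ramp_midpoint(self):
        # single center tap, horizontal linear ramp: delta=(0, 0.5) reads
        # the bilinear midpoint value x + 0.5 exactly
        H = W = 6
        ramp = np.tile(np.arange(W, dtype=np.float64), (H, 1))[None]
        w = np.zeros((1, 1, 9))
        w[0, 0, 4] = 1.0  # center tap of the row-major 3x3 grid
        offs = np.zeros((18, H, W))
        offs[9] = 0.5     # tap 4 dx component (taps are (dy, dx) pairs)
        out = deformable_conv(ramp, DeformableKernelParams(
            weights=w, offsets=offs, modulations=np.ones((9, H, W))))
        expect = ramp[0] + 0.5
        assert np.abs(out[0, :, :W - 1] - expect[:, :W - 1]).max() < 1e-12

    def test_wrong_tap_count(self):
        with pytest.raises(ValueError):
            DeformableKernelParams(weights=np.zeros((1, 1, 9)),
                                   offsets=np.zeros((18, 4, 4)),
                                   modulations=np.ones((9, 4, 4)),
                                   base_offsets=BASE_OFFSETS[:5])

    def test_nonfinite_offsets(self):
        offs = np.zeros((18, 4, 4))
        offs[0, 0, 0] = np.inf
        with pytest.raises(ValueError):
            DeformableKernelParams(weights=np.zeros((1, 1, 9)),
                                   offsets=offs,
                                   modulations=np.ones((9, 4, 4)))

    def test_modulation_range_enforced(self):
        with pytest.raises(ValueError):
            DeformableKernelParams(weights=np.zeros((1, 1, 9)),
                                   offsets=np.zeros((18, 4, 4)),
                                   modulations=np.full((9, 4, 4), 1.5))

    def test_purity(self, rng64):
        x = rng64.standard_normal((2, 5, 5))
        params = DeformableKernelParams(
            weights=rng64.standard_normal((2, 2, 9)),
            offsets=rng64.standard_normal((18, 5, 5)) * 0.3,
            modulations=rng64.random((9, 5, 5)))
        a = deformable_conv(x, params)
        b = deformable_conv(x, params)
        assert np.array_equal(a, b)


class TestLearnOffsets:
    def test_zero_init_predictor(self, rng):
        pred = OffsetPredictor(3, rng, dtype=np.float64)
        offs, mods = learn_offsets(rng.standard_normal((3, 6, 6)), pred)
        assert np.all(offs == 0.0)
        assert np.allclose(mods, 0.5)

    def test_shapes(self, rng):
        pred = OffsetPredictor(2, rng)
        offs, mods = learn_offsets(
            rng.standard_normal((2, 5, 7)).astype(np.float32), pred)
        assert offs.shape == (18, 5, 7)
        assert mods.shape == (9, 5, 7)

    def test_modulations_bounded_100_draws(self, rng):
        for _ in range(100):
            pred = OffsetPredictor(1, rng, dtype=np.float64)
            pred.conv.weight.data = rng.standard_normal(
                pred.conv.weight.data.shape) * 3
            pred.conv.bias.data = rng.standard_normal(27) * 3
            _, mods = learn_offsets(rng.standard_normal((1, 4, 4)), pred)
            assert mods.min() >= 0.0 and mods.max() <= 1.0


class TestPointwiseConv:
    def test_identity(self, rng64):
        x = rng64.standard_normal((3, 4, 5))
        out = pointwise_conv(x, np.eye(3))
        assert np.allclose(out, x, atol=1e-15)

    def test_channel_mean(self, rng64):
        x = rng64.standard_normal((4, 3, 3))
        out = pointwise_conv(x, np.full((1, 4), 0.25))
        assert np.allclose(out[0], x.mean(axis=0), atol=1e-14)

    def test_matches_per_pixel_matmul_oracle(self, rng64):
        x = rng64.standard_normal((5, 4, 4))
        w = rng64.standard_normal((3, 5))
        out = pointwise_conv(x, w)
        for i in range(4):
            for j in range(4):
                assert np.abs(out[:, i, j] - w @ x[:, i, j]).max() < 1e-10

    def test_channel_mismatch(self, rng64):
        with pytest.raises(ValueError):
            pointwise_conv(rng64.standard_normal((3, 2, 2)),
                           np.zeros((2, 4)))


def _nonlocal_oracle(x, block):
    """O((HW)^2) double sum of the embedded-Gaussian attention."""
    C = x.shape[0]
    th = block.theta.weight.data[:, :, 0, 0]
    ph = block.phi.weight.data[:, :, 0, 0]
    gw = block.g.weight.data[:, :, 0, 0]
    xf = x.reshape(C, -1)
    n = xf.shape[1]
    out = np.zeros_like(xf)
    for i in range(n):
        logits = np.array([(th @ xf[:, i]) @ (ph @ xf[:, j])
                           for j in range(n)])
        aff = np.exp(logits - logits.max())
        aff /= aff.sum()
        out[:, i] = sum(aff[j] * (gw @ xf[:, j]) for j in range(n))
    return out.reshape(x.shape)


class TestNonLocal:
    def test_single_pixel_returns_value_embedding(self, rng64):
        blk = NonLocalBlock(3, rng64, NonLocalConfig(residual=False),
                            dtype=np.float64)
        x = rng64.standard_normal((3, 1, 1))
        out = nonlocal_block(x, blk)
        gw = blk.g.weight.data[:, :, 0, 0]
        assert np.allclose(out[:, 0, 0], gw @ x[:, 0, 0], atol=1e-12)

    def test_constant_input_identity_value(self, rng64):
        blk = NonLocalBlock(2, rng64, NonLocalConfig(residual=False),
                            dtype=np.float64)
        blk.g.weight.data = np.eye(2)[:, :, None, None]
        x = np.full((2, 4, 4), 1.7)
        out = nonlocal_block(x, blk)
        assert np.allclose(out, x, atol=1e-12)

    def test_oracle_all_maps_up_to_6x6(self, rng64):
        blk = NonLocalBlock(3, rng64, NonLocalConfig(residual=False),
                            dtype=np.float64)
        for H in range(1, 7):
            for W in range(1, 7):
                x = rng64.standard_normal((3, H, W))
                out = nonlocal_block(x, blk)
                assert np.abs(out - _nonlocal_oracle(x, blk)).max() < 1e-8

    def test_residual_adds_input(self, rng64):
        cfg_res = NonLocalConfig(residual=True)
        blk = NonLocalBlock(2, np.random.default_rng(7), cfg_res,
                            dtype=np.float64)
        blk_no = NonLocalBlock(2, np.random.default_rng(7),
                               NonLocalConfig(residual=False),
                               dtype=np.float64)
        x = rng64.standard_normal((2, 3, 3))
        assert np.allclose(nonlocal_block(x, blk),
                           nonlocal_block(x, blk_no) + x, atol=1e-12)

    def test_affinity_rows_sum_to_one(self, rng64):
        blk = NonLocalBlock(2, rng64, dtype=np.float64)
        A = blk.affinity(Tensor(rng64.standard_normal((1, 2, 4, 4))))
        assert np.allclose(A.sum(axis=-1), 1.0, atol=1e-12)


class TestPatchify:
    def test_token_arithmetic(self, rng64):
        seq = patchify(rng64.standard_normal((1, 8, 8)), 2)
        assert seq.tokens.shape == (16, 4)
        assert seq.grid == (4, 4)

    def test_roundtrip(self, rng64):
        x = rng64.standard_normal((3, 6, 10))
        assert np.array_equal(unpatchify(patchify(x, 2)), x)

    def test_non_divisible(self, rng64):
        with pytest.raises(ValueError):
            patchify(rng64.standard_normal((1, 7, 8)), 2)

    def test_token_layout_channels_rows_cols(self):
        x = np.arange(2 * 4 * 4).reshape(2, 4, 4).astype(float)
        seq = patchify(x, 2)
        # token 0 covers rows 0:2, cols 0:2 of both channels
        expect = np.concatenate([x[0, :2, :2].ravel(), x[1, :2, :2].ravel()])
        assert np.array_equal(seq.tokens[0], expect)


class TestPatchTransformer:
    def test_shape_preserved(self, rng):
        model = PatchTransformer(8, rng, dtype=np.float64)
        seq = patchify(np.random.default_rng(0).standard_normal((2, 4, 4)), 2)
        out = patch_transformer(seq, model)
        assert out.tokens.shape == seq.tokens.shape

    def test_attention_rows_sum_to_one(self, rng):
        model = PatchTransformer(8, rng, dtype=np.float64)
        x = Tensor(np.random.default_rng(1).standard_normal((1, 6, 8)))
        A = model.layers[0].attn.attention_rows(model.layers[0].ln1(x))
        assert A.shape == (1, 4, 6, 6)
        assert np.allclose(A.sum(axis=-1), 1.0, atol=1e-12)

    def test_permutation_equivariance(self, rng):
        # no positional encoding: permuting tokens permutes outputs
        model = PatchTransformer(8, rng, dtype=np.float64)
        tokens = np.random.default_rng(2).standard_normal((8, 8))
        perm = np.random.default_rng(3).permutation(8)
        seq = PatchSequence(tokens, 2, (2, 4), 2)
        seq_p = PatchSequence(tokens[perm], 2, (2, 4), 2)
        out = patch_transformer(seq, model).tokens
        out_p = patch_transformer(seq_p, model).tokens
        assert np.allclose(out_p, out[perm], atol=1e-10)

    def test_head_divisibility(self, rng):
        with pytest.raises(ValueError):
            PatchTransformer(10, rng, heads=4)


class TestPixelShuffle:
    def test_forced_shape(self, rng64):
        out = pixel_shuffle(rng64.standard_normal((4, 3, 3)), 2)
        assert out.shape == (1, 6, 6)

    def test_roundtrip(self, rng64):
        x = rng64.standard_normal((8, 3, 5))
        assert np.array_equal(pixel_unshuffle(pixel_shuffle(x, 2), 2), x)

    def test_index_formula_on_counter(self):
        x = np.arange(4 * 2 * 2).reshape(4, 2, 2).astype(float)
        out = pixel_shuffle(x, 2)
        for c in range(1):
            for h in range(4):
                for w in range(4):
                    src = (c * 4 + (h % 2) * 2 + (w % 2), h // 2, w // 2)
                    assert out[c, h, w] == x[src]

    def test_element_count_conserved(self, rng64):
        x = rng64.standard_normal((12, 4, 6))
        assert pixel_shuffle(x, 2).size == x.size

    def test_divisibility_error(self, rng64):
        with pytest.raises(ValueError):
            pixel_shuffle(rng64.standard_normal((3, 4, 4)), 2)
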