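import numpy as np
import pytest

from retinasr._tensor import Tensor, no_grad
from retinasr.refinenet_u import (BaselineCNN, ClassifierOutput, RefineNetU,
                                  TrainClfConfig, UNetConfig, classify_head,
                                  cross_entropy, leaky_relu, load_clf_checkpoint,
                                  predict, predict_batch, relu,
                                  save_clf_checkpoint, train_classifier)

SMALL = UNetConfig(encoder_filters=(4, 8, 16, 32), input_side=32,
                   dtype="float64")


@pytest.fixture(scope="module")
def small_model():
    return RefineNetU(SMALL, seed=0).eval()


class TestActivations:
    def test_relu_values(self):
        assert relu(-3) == 0 and relu(2) == 2

    def test_leaky_values(self):
        assert leaky_relu(-2, 0.01) == pytest.approx(-0.02)
        assert leaky_relu(0.0, 0.3) == 0.0

    def test_leaky_equals_relu_nonnegative(self, rng64):
        x = np.abs(rng64.standard_normal(20))
        assert np.array_equal(leaky_relu(x, 0.07), relu(x))

    def test_leaky_slope_validated(self):
        with pytest.raises(ValueError):
            leaky_relu(1.0, 1.5)


class TestConfig:
    def test_filter_symmetry(self):
        cfg = UNetConfig()
        assert cfg.decoder_filters == tuple(reversed(cfg.encoder_filters))
        assert cfg.bridge_filters == 2 * cfg.encoder_filters[-1]

    def test_input_side_divisibility(self):
        with pytest.raises(ValueError):
            UNetConfig(input_side=100)


class TestStages:
    def test_shape_ladder_small(self, small_model):
        x = Tensor(np.zeros((1, 1, 32, 32)))
        with no_grad():
            pooled, skips = small_model.encoder_forward(x)
            b = small_model.bridge_forward(pooled)
            d = small_model.decoder_forward(b, skips)
        assert [s.data.shape[2] for s in skips] == [32, 16, 8, 4]
        assert [s.data.shape[1] for s in skips] == [4, 8, 16, 32]
        assert pooled.data.shape == (1, 32, 2, 2)
        assert b.data.shape == (1, 64, 2, 2)
        assert d.data.shape == (1, 4, 32, 32)

    def test_bottleneck_side_forced_arithmetic(self):
        # 112-pixel input: four 2x poolings leave side 7
        model = RefineNetU(UNetConfig(encoder_filters=(2, 4, 8, 16),
                                      input_side=112), seed=0).eval()
        with no_grad():
            pooled, _ = model.encoder_forward(
                Tensor(np.zeros((1, 1, 112, 112), np.float32)))
        assert pooled.data.shape[2] == 7

    def test_bad_input_side(self, small_model):
        with pytest.raises(ValueError):
            small_model.encoder_forward(Tensor(np.zeros((1, 1, 30, 30))))

    def test_bridge_preserves_side_and_is_finite(self, rng):
        model = RefineNetU(SMALL, seed=2).eval()
        for _ in range(100):
            x = Tensor(rng.standard_normal((1, 32, 3, 3)))
            with no_grad():
                out = model.bridge_forward(x)
            assert out.data.shape == (1, 64, 3, 3)
            assert np.all(np.isfinite(out.data))

    def test_decoder_concat_doubles_channels(self, small_model):
        # first decoder stage: upsampled 32 channels + skip 32 -> conv in 64
        up, conv1, _ = small_model.dec[0]
        assert conv1.conv.weight.data.shape[1] == 2 * up.weight.data.shape[1] \
            or conv1.conv.weight.data.shape[1] == 2 * up.weight.data.shape[0]

    def test_skip_mismatch_raises(self, small_model):
        b = Tensor(np.zeros((1, 64, 2, 2)))
        bad_skips = [Tensor(np.zeros((1, f, 5, 5)))
                     for f in (4, 8, 16, 32)]
        with pytest.raises(ValueError):
            small_model.decoder_forward(b, bad_skips)


class TestHead:
    def test_zero_logits_uniform_probs(self, small_model):
        small_model.dense2.weight.data[...] = 0
        small_model.dense2.bias.data[...] = 0
        out = classify_head(np.zeros((4, 32, 32)), small_model)
        assert np.allclose(out.probs, 0.2, atol=1e-12)

    def test_probs_sum_to_one(self, rng64):
        model = RefineNetU(SMALL, seed=5)
        out = classify_head(rng64.standard_normal((4, 32, 32)), model)
        assert abs(out.probs.sum() - 1.0) < 1e-9

    def test_softmax_shift_invariance(self, rng64):
        logits = rng64.standard_normal(5)
        a = Tensor(logits).softmax(-1).data
        b = Tensor(logits + 17.3).softmax(-1).data
        assert np.allclose(a, b, atol=1e-12)

    def test_dropout_inactive_at_inference(self, rng64):
        model = RefineNetU(SMALL, seed=6)
        d = rng64.standard_normal((4, 32, 32))
        a = classify_head(d, model)
        b = classify_head(d, model)
        assert np.array_equal(a.probs, b.probs)


class TestCrossEntropy:
    def test_perfect_prediction_zero(self):
        probs = np.array([[0, 0, 1, 0, 0]], dtype=float)
        labels = np.array([[0, 0, 1, 0, 0]], dtype=float)
        assert cross_entropy(probs, labels) == 0.0

    def test_uniform_ln5(self):
        probs = np.full((3, 5), 0.2)
        labels = np.eye(5)[:3]
        assert abs(cross_entropy(probs, labels) - np.log(5)) < 1e-12

    def test_matches_summation_oracle(self, rng64):
        raw = rng64.random((4, 5)) + 0.01
        probs = raw / raw.sum(axis=1, keepdims=True)
        labels = np.eye(5)[rng64.integers(0, 5, 4)]
        acc = 0.0
        for n in range(4):
            for c in range(5):
                if labels[n, c]:
                    acc -= np.log(probs[n, c])
        assert abs(cross_entropy(probs, labels) - acc / 4) < 1e-10

    def test_rejects_non_onehot(self):
        probs = np.full((1, 5), 0.2)
        with pytest.raises(ValueError):
            cross_entropy(probs, np.array([[0.5, 0.5, 0, 0, 0]]))


class TestPredict:
    def test_argmax(self):
        assert predict(np.array([0.1, 0.6, 0.1, 0.1, 0.1])) == 1

    def test_uniform_tie_breaks_low(self):
        assert predict(np.full(5, 0.2)) == 0

    def test_monotone_invariance(self, rng64):
        for _ in range(20):
            raw = rng64.random(5) + 1e-3
            probs = raw / raw.sum()
            a = rng64.uniform(0.5, 3.0)
            transformed = np.exp(a * probs) + 1.0  # strictly increasing
            assert predict(probs) == predict(transformed)


class TestClassifierOutput:
    def test_validates_simplex(self):
        with pytest.raises(ValueError):
            ClassifierOutput(logits=np.zeros(5),
                             probs=np.array([0.5, 0.5, 0.5, 0, 0]),
                             predicted=0)


class TestBaselineCNN:
    def test_probs_and_length(self, rng):
        model = BaselineCNN(input_side=32, seed=0)
        probs = predict_batch(model, [rng.uniform(-1, 1, (32, 32))])
        assert probs.shape == (1, 5)
        assert abs(probs.sum() - 1.0) < 1e-6

    def test_functional_forward(self, rng):
        from retinasr.refinenet_u import baseline_cnn_forward
        model = BaselineCNN(input_side=32, seed=1)
        out = baseline_cnn_forward(rng.uniform(-1, 1, (32, 32)), model)
        assert out.probs.shape == (5,)
        assert abs(out.probs.sum() - 1.0) < 1e-9
        assert out.predicted == int(np.argmax(out.probs))

    def test_fewer_parameters_than_refinenet(self):
        side = 112
        baseline = BaselineCNN(input_side=side, seed=0)
        unet = RefineNetU(UNetConfig(encoder_filters=(16, 32, 64, 128),
                                     input_side=side), seed=0)
        assert baseline.n_parameters() < unet.n_parameters()

    def test_input_side_check(self):
        with pytest.raises(ValueError):
            BaselineCNN(input_side=30)


def _toy_two_grade_set(n=20, side=16, seed=0):
    """Class 0: bright top half; class 2: bright bottom half (plus noise)."""
    g = np.random.default_rng(seed)
    data = []
    for i in range(n):
        img = g.normal(0, 0.1, (side, side))
        grade = 0 if i % 2 == 0 else 2
        if grade == 0:
            img[: side // 2] += 1.0
        else:
            img[side // 2:] += 1.0
        data.append((img.astype(np.float32), grade))
    return data


class TestTraining:
    def test_overfits_toy_set(self):
        data = _toy_two_grade_set()
        model = RefineNetU(UNetConfig(encoder_filters=(4, 4, 8, 8),
                                      input_side=16), seed=0)
        hist = train_classifier(model, data,
                                TrainClfConfig(epochs=200, batch_size=10,
                                               lr=1e-3), seed=0)
        assert max(hist["accuracy"]) == 1.0

    def test_seed_determinism(self):
        data = _toy_two_grade_set(n=10)
        hists = []
        for _ in range(2):
            model = RefineNetU(UNetConfig(encoder_filters=(4, 4, 8, 8),
                                          input_side=16), seed=3)
            hists.append(train_classifier(
                model, data, TrainClfConfig(epochs=2, batch_size=5, lr=1e-3),
                seed=11))
        assert hists[0] == hists[1]

    def test_single_class_rejected(self):
        data = [(np.zeros((16, 16), np.float32), 1) for _ in range(4)]
        model = RefineNetU(UNetConfig(encoder_filters=(4, 4, 8, 8),
                                      input_side=16), seed=0)
        with pytest.raises(ValueError):
            train_classifier(model, data, TrainClfConfig(epochs=1), seed=0)

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        model = RefineNetU(UNetConfig(encoder_filters=(4, 4, 8, 8),
                                      input_side=16), seed=0)
        img = rng.uniform(-1, 1, (16, 16))
        before = predict_batch(model, [img])
        save_clf_checkpoint(model, tmp_path / "clf")
        back = load_clf_checkpoint(tmp_path / "clf")
        assert np.array_equal(before, predict_batch(back, [img]))


class TestGradientCheck:
    def test_numeric_vs_analytic_on_sampled_params(self):
        """Loss gradient on ~20 sampled parameters of a tiny model agrees
        with central differences to 1e-4 relative."""
        cfg = UNetConfig(encoder_filters=(2, 2, 4, 4), input_side=16,
                         dtype="float64", encoder_dropout=0.0,
                         head_dropout=0.0, batch_norm=False)
        model = RefineNetU(cfg, seed=0)
        g = np.random.default_rng(0)
        x = Tensor(g.uniform(-1, 1, (2, 1, 16, 16)))
        y = np.eye(5)[[1, 3]]

        def loss_value():
            model.eval()
            logits = model(x)
            return -(logits.log_softmax(axis=-1) * Tensor(y)).sum() * 0.5

        loss = loss_value()
        loss.backward()
        params = model.parameters()
        picked = []
        for p in params:
            flat_idx = int(g.integers(0, p.data.size))
            picked.append((p, np.unravel_index(flat_idx, p.data.shape)))
            if len(picked) >= 20:
                break
        for p, idx in picked:
            orig = p.data[idx]
            eps = 1e-5
            p.data[idx] = orig + eps
            f1 = float(loss_value().data)
            p.data[idx] = orig - eps
            f2 = float(loss_value().data)
            p.data[idx] = orig
            num = (f1 - f2) / (2 * eps)
            ana = p.grad[idx]
            denom = max(abs(num), abs(ana), 1e-8)
            assert abs(num - ana) / denom < 1e-4
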