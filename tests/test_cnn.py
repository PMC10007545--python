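"""CNN architecture, parameter accounting, training behaviour, feature extraction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.signal import correlate

from auscult.cnn import CNNSpec, HeartLungCNN, TrainingConfig, conv_param_count, param_counts
from auscult.nnet import Conv2D, Dense, MaxPool2D, softmax_xent, zero_grads


class TestParamCounts:
    def test_published_layer_counts(self):
        counts = param_counts()
        assert counts["conv1"] == 624
        assert counts["conv2"] == 28_848
        assert counts["conv3"] == 6_928
        assert counts["conv_total"] == 36_400

    def test_one_by_one_conv_has_weight_plus_bias(self):
        assert conv_param_count(1, 1, 1, 1) == 2

    def test_dense_layers_reported_separately(self):
        counts = param_counts()
        assert counts["dense"] == (16_384 + 1) * 64
        assert counts["total"] == counts["conv_total"] + counts["dense"] + counts["head"]

    @given(st.integers(1, 4), st.integers(1, 4), st.integers(1, 3), st.integers(1, 5))
    def test_formula_matches_exhaustive_weight_enumeration(self, kh, kw, cin, cout):
        layer = Conv2D(kh, kw, cin, cout, rng=np.random.default_rng(0))
        assert layer.n_params == layer.w.size + layer.b.size
        assert layer.n_params == conv_param_count(kh, kw, cin, cout)


class TestConvCorrectness:
    def test_forward_matches_scipy_correlate(self, rng):
        x = rng.standard_normal((2, 10, 12, 3)).astype(np.float32)
        layer = Conv2D(3, 3, 3, 4, stride=(1, 1), relu=False, rng=rng)
        out = layer.forward(x)
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        for b in range(2):
            for co in range(4):
                ref = sum(correlate(xp[b, :, :, ci], layer.w[:, :, ci, co], mode="valid")
                          for ci in range(3)) + layer.b[co]
                assert np.allclose(out[b, :, :, co], ref, atol=1e-4)

    def test_strided_forward_matches_scipy_with_same_padding(self, rng):
        x = rng.standard_normal((1, 16, 16, 2)).astype(np.float32)
        layer = Conv2D(5, 5, 2, 3, stride=(4, 2), relu=False, rng=np.random.default_rng(3))
        out = layer.forward(x)
        # SAME-pad arithmetic re-derived here: out = ceil(in/stride),
        # pad_total = (out-1)*stride + k - in, excess at the end
        def pads(size, k, s):
            o = -(-size // s)
            p = max((o - 1) * s + k - size, 0)
            return p // 2, p - p // 2
        (pt, pb), (pl, pr) = pads(16, 5, 4), pads(16, 5, 2)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        for co in range(3):
            ref = sum(correlate(xp[0, :, :, ci], layer.w[:, :, ci, co], mode="valid")
                      for ci in range(2))[::4, ::2] + layer.b[co]
            assert np.allclose(out[0, :, :, co], ref, atol=1e-5)

    def test_backward_matches_numerical_gradient(self, rng):
        x = rng.standard_normal((2, 8, 8, 1)).astype(np.float32)
        y = np.array([0, 2])
        conv = Conv2D(3, 3, 1, 3, stride=(2, 1), relu=True, rng=rng)
        pool = MaxPool2D(2, 2)
        dense = Dense(2 * 4 * 3, 4, rng=rng)

        def forward(train=False):
            h = pool.forward(conv.forward(x, train), train)
            return softmax_xent(dense.forward(h.reshape(2, -1), train), y)

        zero_grads([conv, dense])
        _, dlog = forward(train=True)
        conv.backward(pool.backward(dense.backward(dlog).reshape(2, 2, 4, 3)))
        eps = 1e-3
        for p, g in (conv.params()[0], conv.params()[1], dense.params()[0]):
            idx = tuple(rng.integers(0, s) for s in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            lp, _ = forward()
            p[idx] = orig - eps
            lm, _ = forward()
            p[idx] = orig
            assert g[idx] == pytest.approx((lp - lm) / (2 * eps), rel=2e-2, abs=1e-4)


class TestMaxPool:
    def test_matches_naive_block_maximum(self, rng):
        x = rng.standard_normal((3, 8, 6, 5)).astype(np.float32)
        out = MaxPool2D(4, 2).forward(x)
        ref = x.reshape(3, 2, 4, 3, 2, 5).max(axis=(2, 4))
        assert np.allclose(out, ref)

    def test_gradient_routes_to_argmax_only(self, rng):
        x = rng.standard_normal((1, 4, 4, 1)).astype(np.float32)
        pool = MaxPool2D(2, 2)
        out = pool.forward(x, train=True)
        d = np.ones_like(out)
        dx = pool.backward(d)
        assert dx.sum() == pytest.approx(out.size)
        assert ((dx != 0).sum()) == out.size


class TestTraining:
    def test_separable_two_class_toy_reaches_full_accuracy(self):
        spec = CNNSpec(input_size=64)
        rng = np.random.default_rng(0)
        blank = np.zeros((10, 64, 64), dtype=np.float32)
        square = np.zeros((10, 64, 64), dtype=np.float32)
        square[:, 20:40, 20:40] = 1.0
        x = np.concatenate([blank, square]) + 0.01 * rng.random((20, 64, 64)).astype(np.float32)
        y = np.array([0] * 10 + [1] * 10)
        model = HeartLungCNN(spec, seed=0)
        model.train_classifier(x, y, TrainingConfig(epochs=5, batch_size=8, seed=0))
        assert np.mean(model.predict(x) == y) == 1.0

    def test_same_seed_reproduces_loss_history(self):
        spec = CNNSpec(input_size=64)
        rng = np.random.default_rng(1)
        x = rng.random((12, 64, 64)).astype(np.float32)
        y = rng.integers(0, 3, 12)
        h1 = HeartLungCNN(spec, seed=5).train_classifier(
            x, y, TrainingConfig(epochs=3, batch_size=4, seed=5))
        h2 = HeartLungCNN(spec, seed=5).train_classifier(
            x, y, TrainingConfig(epochs=3, batch_size=4, seed=5))
        assert np.allclose(h1, h2, rtol=1e-6)

    def test_missing_class_warns(self):
        spec = CNNSpec(input_size=64)
        x = np.random.default_rng(2).random((6, 64, 64)).astype(np.float32)
        y = np.zeros(6, dtype=int)
        with pytest.warns(UserWarning, match="classes present"):
            HeartLungCNN(spec, seed=0).train_classifier(
                x, y, TrainingConfig(epochs=1, batch_size=4))


class TestFeatures:
    @pytest.fixture(scope="class")
    def model(self):
        return HeartLungCNN(CNNSpec(), seed=0)

    def test_sixty_four_finite_reals(self, model, rng):
        f = model.features(rng.random((256, 256)).astype(np.float32))
        assert f.shape == (64,)
        assert np.isfinite(f).all()

    def test_identical_images_identical_vectors(self, model, rng):
        img = rng.random((256, 256)).astype(np.float32)
        assert np.array_equal(model.features(img), model.features(img.copy()))

    def test_independent_of_batch_composition(self, model, rng):
        imgs = rng.random((5, 256, 256)).astype(np.float32)
        batch = model.features(imgs)
        solo = np.stack([model.features(imgs[i]) for i in range(5)])
        assert np.allclose(batch, solo, atol=1e-5)

    def test_distinct_images_yield_distinct_vectors(self, model, rng):
        blank = np.zeros((256, 256), dtype=np.float32)
        bright = rng.random((256, 256)).astype(np.float32)
        diff = np.linalg.norm(model.features(blank) - model.features(bright))
        assert diff > 0.0

    def test_wrong_shape_rejected(self, model):
        with pytest.raises(ValueError):
            model.features(np.zeros((5, 128, 128), dtype=np.float32))


class TestPersistence:
    def test_save_load_roundtrip_preserves_outputs(self, tmp_path, rng):
        spec = CNNSpec(input_size=64)
        model = HeartLungCNN(spec, seed=3)
        img = rng.random((64, 64)).astype(np.float32)
        model.save(tmp_path / "m.npz")
        back = HeartLungCNN.load(tmp_path / "m.npz")
        assert np.allclose(model.features(img), back.features(img))

    def test_training_config_validation(self):
        with pytest.raises(ValueError):
            TrainingConfig(epochs=0)
        cfg = TrainingConfig()
        assert (cfg.epochs, cfg.batch_size) == (100, 128)
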