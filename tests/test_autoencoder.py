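import numpy as np
import pytest
from skimage.metrics import structural_similarity

from ecgrqa import AEConfig, ConvAutoencoder, ae_loss, build_autoencoder, \
    encode, mssim, train_autoencoder
from ecgrqa._nn.autograd import Tensor, conv2d, conv_transpose2d


def _numeric_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


class TestAutogradConv:
    """Gradient checks of the convolution primitives the models rely on."""

    def test_conv2d_gradients(self):
        rng = np.random.default_rng(0)
        x = Tensor(rng.standard_normal((2, 3, 6, 6)), requires_grad=True)
        w = Tensor(rng.standard_normal((4, 3, 4, 4)) * 0.3,
                   requires_grad=True)
        out = conv2d(x, w, stride=2, padding=1).sigmoid().mean()
        out.backward()

        def f():
            return float(conv2d(Tensor(x.data), Tensor(w.data), stride=2,
                                padding=1).sigmoid().mean().data)

        assert np.abs(x.grad - _numeric_grad(f, x.data)).max() < 1e-7
        assert np.abs(w.grad - _numeric_grad(f, w.data)).max() < 1e-7

    def test_conv_transpose_gradients_and_shape(self):
        rng = np.random.default_rng(1)
        x = Tensor(rng.standard_normal((2, 4, 3, 3)), requires_grad=True)
        w = Tensor(rng.standard_normal((4, 3, 4, 4)) * 0.3,
                   requires_grad=True)
        out = conv_transpose2d(x, w, stride=2, padding=1)
        assert out.shape == (2, 3, 6, 6)
        loss = out.abs().mean()
        loss.backward()

        def f():
            return float(conv_transpose2d(Tensor(x.data), Tensor(w.data),
                                          stride=2, padding=1)
                         .abs().mean().data)

        assert np.abs(x.grad - _numeric_grad(f, x.data)).max() < 1e-7
        assert np.abs(w.grad - _numeric_grad(f, w.data)).max() < 1e-7


class TestMssim:
    def test_identical_images_give_one(self):
        rng = np.random.default_rng(2)
        x = rng.random((2, 24, 24))
        assert mssim(x, x) == pytest.approx(1.0)

    def test_inverted_image_below_one(self):
        x = np.zeros((24, 24))
        x[::2] = 1.0
        assert mssim(x, 1.0 - x) < 1.0

    def test_matches_independent_ssim_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(3):
            a = rng.random((32, 32))
            b = np.clip(a + rng.normal(0, 0.2, a.shape), 0, 1)
            ref = structural_similarity(
                a, b, win_size=11, sigma=1.5, gaussian_weights=True,
                use_sample_covariance=False, data_range=1.0)
            assert mssim(a, b) == pytest.approx(ref, abs=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            mssim(np.zeros((16, 16)), np.zeros((17, 17)))


class TestAeLoss:
    def test_zero_at_identity(self):
        rng = np.random.default_rng(4)
        x = rng.random((3, 20, 20))
        assert ae_loss(x, x) == pytest.approx(0.0)

    def test_constant_offset_l1_term_exact(self):
        rng = np.random.default_rng(5)
        x = rng.random((20, 20)) * 0.8
        shifted = x + 0.1
        l1 = np.abs(x - shifted).mean()
        assert l1 == pytest.approx(0.1)
        total = ae_loss(x, shifted)
        ms = mssim(x, shifted)
        assert total == pytest.approx(0.1 + (1.0 - ms))

    def test_nonnegative_for_nonneg_ssim(self):
        rng = np.random.default_rng(6)
        x, y = rng.random((20, 20)), rng.random((20, 20))
        if mssim(x, y) >= 0:
            assert ae_loss(x, y) >= 0.0


class TestArchitecture:
    def test_latent_shape_contract(self):
        rng = np.random.default_rng(7)
        X = rng.random((3, 1, 64, 64))
        ae = ConvAutoencoder(latent_side=8, widths=(4, 8), epochs=0, seed=0)
        ae.fit(X)
        z = ae.transform(X)
        assert z.shape == (3, 8, 8)
        rec = ae.reconstruct(X)
        assert rec.shape == X.shape

    def test_unreachable_latent_rejected(self):
        cfg = AEConfig(input_channels=1, input_size=60, latent_side=8,
                       epochs=0)
        with pytest.raises(ValueError, match="not reachable"):
            build_autoencoder(cfg)

    def test_build_matches_config_shapes(self):
        ae = build_autoencoder(AEConfig(input_channels=2, input_size=32,
                                        latent_side=8, epochs=0))
        z = ae.transform(np.random.default_rng(0).random((2, 2, 32, 32)))
        assert z.shape == (2, 8, 8)

    def test_encode_wrapper_and_determinism(self):
        rng = np.random.default_rng(8)
        X = rng.random((2, 1, 32, 32))
        ae = ConvAutoencoder(latent_side=8, widths=(4,), epochs=0, seed=1)
        ae.fit(X)
        z1 = encode(ae, X[0]).grid
        z2 = encode(ae, X[0]).grid
        assert np.array_equal(z1, z2)
        assert np.all(np.isfinite(z1))


class TestTraining:
    def test_zero_epochs_history_empty(self):
        rng = np.random.default_rng(9)
        model, hist = train_autoencoder(rng.random((2, 1, 16, 16)),
                                        AEConfig(1, 16, 4, epochs=0))
        assert hist.train_loss == []

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(10)
        X = rng.random((6, 1, 32, 32))
        curves = []
        for _ in range(2):
            ae = ConvAutoencoder(latent_side=8, widths=(4,), epochs=3,
                                 batch_size=4, seed=42)
            ae.fit(X)
            curves.append(ae.history_.train_loss)
        assert curves[0] == curves[1]

    def test_loss_decreases(self):
        rng = np.random.default_rng(11)
        base = np.zeros((1, 24, 24))
        base[0, 8:16, 8:16] = 1.0
        X = np.stack([np.clip(base + rng.normal(0, 0.05, base.shape), 0, 1)
                      for _ in range(8)])
        ae = ConvAutoencoder(latent_side=6, widths=(4,), epochs=25,
                             batch_size=4, seed=0, ssim_window=7)
        ae.fit(X)
        assert ae.history_.train_loss[-1] < ae.history_.train_loss[0]

    def test_overfit_single_repeated_sample(self):
        """A single repeated structured image is memorised at test scale."""
        rng = np.random.default_rng(12)
        img = np.clip(rng.random((1, 32, 32)) * 0.2
                      + np.tri(32)[None], 0, 1)
        X = np.repeat(img[None], 4, axis=0)
        ae = ConvAutoencoder(latent_side=8, widths=(32,), epochs=200,
                             batch_size=4, seed=0, ssim_window=7,
                             learning_rate=2e-2)
        ae.fit(X)
        assert ae.history_.train_loss[-1] < 0.05

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_autoencoder([], AEConfig(1, 16, 4, epochs=1))
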