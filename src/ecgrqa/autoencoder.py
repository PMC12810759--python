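"""Convolutional autoencoder over recurrence-image stacks.

The encoder compresses a C×H×W stack through stride-2 convolution blocks to
a single-channel spatial bottleneck (14×14 for 224-pixel inputs), the
mirrored decoder reconstructs the stack, and training minimises

    L(x) = |x - x~| + (1 - MSSIM(x, x~)),

the mean absolute reconstruction error plus a structural-similarity
penalty.  Both terms are averaged so they share scale; the SSIM term is
differentiated through the same autodiff graph used by the layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._nn import (Adam, Conv2d, ConvTranspose2d, Module, ReLU, Sequential,
                  Sigmoid, Tensor)
from ._nn.autograd import conv2d as _conv
from .recurrence import RPImageStack


@dataclass
class AEConfig:
    """Training configuration for the autoencoder."""

    input_channels: int = 15
    input_size: int = 224
    latent_side: int = 14
    epochs: int = 1000
    batch_size: int = 16
    learning_rate: float = 5e-3
    val_split: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_side < 1:
            raise ValueError("latent_side must be >= 1")
        if not 0.0 < self.val_split < 1.0:
            raise ValueError("val_split must lie in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class LatentEmbedding:
    """Single-channel spatial bottleneck output for one record."""

    grid: np.ndarray
    record_id: str = ""
    label: Optional[str] = None


@dataclass
class TrainHistory:
    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    l1: List[float] = field(default_factory=list)
    mssim: List[float] = field(default_factory=list)


# -- structural similarity -------------------------------------------------

def _gaussian_1d(window: int, sigma: float) -> np.ndarray:
    r = (window - 1) / 2.0
    x = np.arange(window) - r
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def _as_nchw(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[None]
    if x.ndim != 4:
        raise ValueError("expected 2-D, 3-D or 4-D image array")
    return x


def _mssim_graph(x: Tensor, y: Tensor, window: int, sigma: float,
                 data_range: float) -> Tensor:
    """Differentiable mean SSIM over a batch of image stacks."""
    n, c, h, w = x.shape
    if h < window or w < window:
        raise ValueError(f"images ({h}x{w}) smaller than SSIM window {window}")
    g = _gaussian_1d(window, sigma).astype(x.data.dtype)
    krow = Tensor(g.reshape(1, 1, 1, window))
    kcol = Tensor(g.reshape(1, 1, window, 1))

    def filt(t: Tensor) -> Tensor:
        t = t.reshape(n * c, 1, h, w)
        return _conv(_conv(t, kcol), krow)

    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    mu_x, mu_y = filt(x), filt(y)
    sxx = filt(x * x) - mu_x * mu_x
    syy = filt(y * y) - mu_y * mu_y
    sxy = filt(x * y) - mu_x * mu_y
    num = (2.0 * mu_x * mu_y + c1) * (2.0 * sxy + c2)
    den = (mu_x * mu_x + mu_y * mu_y + c1) * (sxx + syy + c2)
    return (num / den).mean()


def mssim(x: np.ndarray, x_rec: np.ndarray, window: int = 11,
          sigma: float = 1.5, data_range: float = 1.0) -> float:
    """Mean structural similarity index between two image stacks.

    Gaussian-weighted windows (Wang et al. parameters by default: 11-pixel
    window, sigma 1.5, population statistics), averaged over all window
    positions and channels.  Equals 1 iff the inputs are identical.
    """
    a, b = _as_nchw(x), _as_nchw(x_rec)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    return float(_mssim_graph(Tensor(a), Tensor(b), window, sigma,
                              data_range).data)


def ae_loss(x: np.ndarray, x_rec: np.ndarray, window: int = 11,
            sigma: float = 1.5, data_range: float = 1.0) -> float:
    """Composite reconstruction loss: mean |x - x~| + (1 - MSSIM)."""
    a, b = _as_nchw(x), _as_nchw(x_rec)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.abs(a - b).mean()
                 + (1.0 - mssim(a, b, window, sigma, data_range)))


# -- model -----------------------------------------------------------------

class _AEModel(Module):
    """Encoder/decoder pair of mirrored stride-2 conv blocks."""

    def __init__(self, channels: int, input_size: int, latent_side: int,
                 widths: Sequence[int], rng: np.random.Generator):
        ratio = input_size / latent_side
        n_blocks = int(round(np.log2(ratio))) if ratio >= 1 else -1
        if n_blocks < 1 or latent_side * 2**n_blocks != input_size:
            raise ValueError(
                f"latent side {latent_side} not reachable from input size "
                f"{input_size} by an integer chain of stride-2 blocks"
            )
        widths = list(widths)
        while len(widths) < n_blocks - 1:
            widths.append(widths[-1])
        chs = [channels] + widths[: n_blocks - 1] + [1]
        enc: List[Module] = []
        for i in range(n_blocks):
            enc.append(Conv2d(chs[i], chs[i + 1], 4, stride=2, padding=1,
                              rng=rng))
            if i < n_blocks - 1:
                enc.append(ReLU())  # linear bottleneck: latent is real-valued
        dec: List[Module] = []
        for i in range(n_blocks, 0, -1):
            dec.append(ConvTranspose2d(chs[i], chs[i - 1], 4, stride=2,
                                       padding=1, rng=rng))
            dec.append(ReLU() if i > 1 else Sigmoid())
        self.encoder = Sequential(*enc)
        self.decoder = Sequential(*dec)

    def forward(self, x: Tensor) -> Tensor:
        return self.decoder(self.encoder(x))


class ConvAutoencoder(BaseEstimator, TransformerMixin):
    """sklearn-style convolutional autoencoder.

    ``fit`` expects an array (n, C, H, W) with values in [0, 1] (H = W a
    power-of-two multiple of ``latent_side``); ``transform`` returns the
    (n, latent_side, latent_side) bottleneck grids.  Deterministic given
    ``seed``.
    """

    def __init__(self, latent_side: int = 14, widths: Tuple[int, ...] = (32, 64, 128),
                 epochs: int = 1000, batch_size: int = 16,
                 learning_rate: float = 5e-3, val_split: float = 0.2,
                 seed: int = 0, ssim_window: int = 11, ssim_sigma: float = 1.5,
                 verbose: int = 0):
        self.latent_side = latent_side
        self.widths = widths
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.val_split = val_split
        self.seed = seed
        self.ssim_window = ssim_window
        self.ssim_sigma = ssim_sigma
        self.verbose = verbose

    def _build(self, channels: int, size: int,
               rng: np.random.Generator) -> _AEModel:
        return _AEModel(channels, size, self.latent_side, self.widths, rng)

    def _loss(self, x: Tensor, rec: Tensor):
        l1 = (x - rec).abs().mean()
        ms = _mssim_graph(x, rec, self.ssim_window, self.ssim_sigma, 1.0)
        return l1 + (1.0 - ms), float(l1.data), float(ms.data)

    def fit(self, X: np.ndarray, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 4:
            raise ValueError("expected stacks of shape (n, C, H, W)")
        if X.shape[0] < 1:
            raise ValueError("empty dataset")
        if X.shape[2] != X.shape[3]:
            raise ValueError("images must be square")
        n, c, size, _ = X.shape
        rng = np.random.default_rng(self.seed)
        self.model_ = self._build(c, size, rng)
        self.n_channels_, self.input_size_ = c, size
        self.history_ = TrainHistory()
        opt = Adam(self.model_.parameters(), lr=self.learning_rate)

        perm = rng.permutation(n)
        n_val = int(round(self.val_split * n)) if n >= 5 else 0
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        for _ in range(self.epochs):
            order = rng.permutation(len(train_idx))
            tot = l1_tot = ms_tot = cnt = 0.0
            for start in range(0, len(order), self.batch_size):
                batch = X[train_idx[order[start:start + self.batch_size]]]
                xb = Tensor(batch.astype(np.float32))
                rec = self.model_(xb)
                loss, l1v, msv = self._loss(xb, rec)
                opt.zero_grad()
                loss.backward()
                opt.step()
                b = batch.shape[0]
                tot += float(loss.data) * b
                l1_tot += l1v * b
                ms_tot += msv * b
                cnt += b
            self.history_.train_loss.append(tot / cnt)
            self.history_.l1.append(l1_tot / cnt)
            self.history_.mssim.append(ms_tot / cnt)
            if n_val:
                xv = Tensor(X[val_idx].astype(np.float32))
                loss_v, _, _ = self._loss(xv, self.model_(xv))
                self.history_.val_loss.append(float(loss_v.data))
            if self.verbose:
                print(f"epoch {len(self.history_.train_loss)}: "
                      f"train {self.history_.train_loss[-1]:.4f}")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("autoencoder is not fitted")
        X = np.asarray(X, dtype=float)
        single = X.ndim == 3
        if single:
            X = X[None]
        if X.shape[1] != self.n_channels_ or X.shape[2] != self.input_size_:
            raise ValueError(
                f"stack shape {X.shape[1:]} does not match fitted shape "
                f"({self.n_channels_}, {self.input_size_}, {self.input_size_})"
            )
        z = self.model_.encoder(Tensor(X.astype(np.float32))).data[:, 0]
        return z[0] if single else z

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        return self.model_(Tensor(X)).data


# -- thin functional wrappers ----------------------------------------------

def build_autoencoder(config: AEConfig) -> ConvAutoencoder:
    """Initialise an (untrained) autoencoder and materialise its layers."""
    ae = ConvAutoencoder(latent_side=config.latent_side,
                         epochs=config.epochs, batch_size=config.batch_size,
                         learning_rate=config.learning_rate,
                         val_split=config.val_split, seed=config.seed)
    rng = np.random.default_rng(config.seed)
    ae.model_ = ae._build(config.input_channels, config.input_size, rng)
    ae.n_channels_ = config.input_channels
    ae.input_size_ = config.input_size
    ae.history_ = TrainHistory()
    return ae


def train_autoencoder(dataset: Sequence[RPImageStack | np.ndarray],
                      config: AEConfig):
    """Train on a list of image stacks; returns ``(model, history)``."""
    if not len(dataset):
        raise ValueError("empty dataset")
    arrs = [s.tensor if isinstance(s, RPImageStack) else np.asarray(s)
            for s in dataset]
    X = np.stack(arrs)
    ae = ConvAutoencoder(latent_side=config.latent_side,
                         epochs=config.epochs, batch_size=config.batch_size,
                         learning_rate=config.learning_rate,
                         val_split=config.val_split, seed=config.seed)
    ae.fit(X)
    return ae, ae.history_


def encode(model: ConvAutoencoder, stack: RPImageStack | np.ndarray
           ) -> LatentEmbedding:
    """Encode one stack to its latent grid (inference is deterministic)."""
    if isinstance(stack, RPImageStack):
        grid = model.transform(stack.tensor)
        return LatentEmbedding(grid=grid, record_id=stack.record_id,
                               label=stack.label)
    return LatentEmbedding(grid=model.transform(np.asarray(stack)))
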