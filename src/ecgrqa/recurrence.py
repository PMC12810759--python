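"""Recurrence matrices, binary recurrence plots and image stacks.

The recurrence matrix holds pairwise Euclidean distances between embedded
state vectors; the binary recurrence plot thresholds it with a Heaviside
step at distance ε.  For the autoencoder, the *unthresholded* min-max
normalised distance matrix is resized to a square grayscale image and the
per-channel images of a record are stacked in canonical channel order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist
from skimage.transform import resize as _sk_resize
from sklearn.base import BaseEstimator, TransformerMixin

from .io_ecg import ECGRecord
from .phase_space import DataMatrix, EmbeddingParams, delay_embed, embed, \
    select_time_lag, cao_embedding_dimension


@dataclass(frozen=True)
class RecurrenceMatrix:
    """K×K symmetric matrix of Euclidean distances between states."""

    dist: np.ndarray
    params: Optional[EmbeddingParams] = None


@dataclass(frozen=True)
class BinaryRP:
    """Heaviside-thresholded recurrence plot."""

    grid: np.ndarray
    epsilon: float
    theiler: int = 0

    @property
    def recurrence_rate(self) -> float:
        return float(self.grid.mean())


@dataclass
class RPImageStack:
    """C×H×W stack of per-channel recurrence images in [0, 1]."""

    tensor: np.ndarray
    record_id: str = ""
    label: Optional[str] = None


def distance_matrix(D: DataMatrix) -> RecurrenceMatrix:
    """Pairwise Euclidean distances between the rows of the data matrix."""
    states = np.asarray(D.states, dtype=float)
    if states.shape[0] < 2:
        raise ValueError("need at least 2 state vectors")
    dist = squareform(pdist(states, metric="euclidean"))
    return RecurrenceMatrix(dist=dist, params=D.params)


def binarize(R: RecurrenceMatrix, policy: str = "epsilon",
             value: float = 0.0, theiler: int = 0) -> BinaryRP:
    """Threshold the distance matrix into a binary recurrence plot.

    ``policy='epsilon'``   : recurrent where dist <= value (value >= 0).
    ``policy='target_rr'`` : ε is the *value*-quantile of the off-diagonal
    distances, so the achieved recurrence rate approximates ``value``.
    A Theiler band |i-j| <= theiler is zeroed after thresholding.
    """
    dist = R.dist
    if policy == "epsilon":
        if value < 0:
            raise ValueError("epsilon must be non-negative")
        eps = float(value)
    elif policy == "target_rr":
        if not 0.0 < value < 1.0:
            raise ValueError("target_rr must lie in (0, 1)")
        off = dist[~np.eye(dist.shape[0], dtype=bool)]
        eps = float(np.quantile(off, value))
    else:
        raise ValueError(f"unknown policy {policy!r}")
    grid = (dist <= eps).astype(np.uint8)
    if theiler:
        i, j = np.indices(grid.shape)
        grid[np.abs(i - j) <= theiler] = 0
    return BinaryRP(grid=grid, epsilon=eps, theiler=theiler)


def resize_to_image(R: RecurrenceMatrix | np.ndarray, size: int = 224,
                    order: int = 1) -> np.ndarray:
    """Min-max normalise the distance matrix and resample to size×size.

    Bilinear interpolation by default (``order=0`` for nearest-neighbour).
    A constant matrix maps to all zeros.
    """
    dist = R.dist if isinstance(R, RecurrenceMatrix) else np.asarray(R, float)
    if dist.shape[0] < 2 or size < 2:
        raise ValueError("matrix side and target size must both be >= 2")
    lo, hi = dist.min(), dist.max()
    norm = np.zeros_like(dist) if hi == lo else (dist - lo) / (hi - lo)
    if norm.shape == (size, size):
        return norm
    img = _sk_resize(norm, (size, size), order=order, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return np.clip(img, 0.0, 1.0)


def stack_channels(images: Sequence[np.ndarray], record_id: str = "",
                   label: Optional[str] = None,
                   channel_names: Optional[Sequence[str]] = None,
                   expected_order: Optional[Sequence[str]] = None,
                   ) -> RPImageStack:
    """Stack per-channel recurrence images into a C×H×W tensor.

    The list order must equal the canonical channel order; when both
    ``channel_names`` and ``expected_order`` are given they are checked.
    """
    if not images:
        raise ValueError("no images to stack")
    shape = images[0].shape
    for c, img in enumerate(images):
        if img.shape != shape:
            name = channel_names[c] if channel_names else f"index {c}"
            raise ValueError(
                f"channel {name}: shape {img.shape} != expected {shape}"
            )
    if channel_names is not None and expected_order is not None:
        if list(channel_names) != list(expected_order):
            raise ValueError(
                f"channel order {list(channel_names)} does not match the "
                f"canonical order {list(expected_order)}"
            )
    return RPImageStack(tensor=np.stack(images).astype(float),
                        record_id=record_id, label=label)


class RecurrencePlotTransformer(BaseEstimator, TransformerMixin):
    """Turn ECG records into stacks of recurrence images.

    Each channel of a record is delay-embedded, its Euclidean distance
    matrix is min-max normalised and resized to ``size``×``size``, and the
    channel images are stacked in record order.  ``transform`` accepts a
    list of :class:`~ecgrqa.io_ecg.ECGRecord` and returns an array of shape
    (n_records, channels, size, size).

    Parameters
    ----------
    size : output image side (224 matches the full-scale pipeline).
    window_s : analysis window in seconds taken from the record start;
        ``None`` uses the whole record.
    tau, M : embedding lag and dimension; either may be ``None`` to
        estimate shared parameters from the first record's reference
        channel (AMI lag, Cao dimension) at fit time.
    mode : ``'distance'`` (continuous grayscale, autoencoder input) or
        ``'binary'`` (thresholded at the ``target_rr`` quantile).
    """

    def __init__(self, size: int = 224, window_s: Optional[float] = 10.0,
                 tau: Optional[int] = None, M: Optional[int] = None,
                 mode: str = "distance", target_rr: float = 0.1,
                 theiler: int = 0, reference_channel: int = 1,
                 m_max: int = 8, max_lag: int = 50):
        self.size = size
        self.window_s = window_s
        self.tau = tau
        self.M = M
        self.mode = mode
        self.target_rr = target_rr
        self.theiler = theiler
        self.reference_channel = reference_channel
        self.m_max = m_max
        self.max_lag = max_lag

    def _window(self, rec: ECGRecord) -> np.ndarray:
        if self.window_s is None:
            return rec.signal
        n = min(rec.n_samples, int(round(self.window_s * rec.fs)))
        return rec.signal[:, :n]

    def fit(self, X: Sequence[ECGRecord], y=None):
        if self.tau is not None and self.M is not None:
            self.tau_, self.M_ = int(self.tau), int(self.M)
            return self
        if not len(X):
            raise ValueError("need at least one record to estimate (tau, M)")
        ref = self._window(X[0])[min(self.reference_channel,
                                     X[0].n_channels - 1)]
        tau = (int(self.tau) if self.tau is not None
               else select_time_lag(ref, "ami", max_lag=self.max_lag))
        if self.M is not None:
            M = int(self.M)
        else:
            M, _, _ = cao_embedding_dimension(ref, tau, m_max=self.m_max)
        self.tau_, self.M_ = tau, M
        return self

    def transform(self, X: Sequence[ECGRecord]) -> np.ndarray:
        if not hasattr(self, "tau_"):
            self.fit(X)
        out = []
        for rec in X:
            sig = self._window(rec)
            imgs = []
            for ch in sig:
                R = distance_matrix(embed(ch, self.tau_, self.M_))
                if self.mode == "binary":
                    b = binarize(R, "target_rr", self.target_rr, self.theiler)
                    imgs.append(resize_to_image(
                        RecurrenceMatrix(b.grid.astype(float)), self.size))
                else:
                    imgs.append(resize_to_image(R, self.size))
            out.append(stack_channels(imgs, rec.record_id, rec.label).tensor)
        return np.asarray(out)

    def transform_record(self, rec: ECGRecord) -> RPImageStack:
        """Single-record convenience returning a tagged :class:`RPImageStack`."""
        t = self.transform([rec])[0]
        return RPImageStack(tensor=t, record_id=rec.record_id, label=rec.label)
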