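"""Time-delay phase-space reconstruction.

A scalar series :math:`\\{x_1,\\dots,x_N\\}` is embedded as K state vectors

.. math:: s_i = (x_i, x_{i+\\tau}, \\dots, x_{i+(M-1)\\tau}),

with K = N - (M-1)τ forced by the embedding.  The time lag τ is chosen from
the first minimum of the average mutual information (or the 1/e crossing of
the autocorrelation), and the minimum embedding dimension M from the
saturation of Cao's E1(m) ratio; Cao's E2(m) additionally separates
deterministic signals (E2 varies with m) from stochastic ones (E2 ≈ 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class EmbeddingParams:
    """Delay-embedding parameters (lag τ, dimension M, signal length N)."""

    tau: int
    M: int
    N: int

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValueError(f"tau must be >= 1, got {self.tau}")
        if self.M < 1:
            raise ValueError(f"M must be >= 1, got {self.M}")
        if self.N < (self.M - 1) * self.tau + 1:
            raise ValueError(
                f"signal length {self.N} too short for M={self.M}, "
                f"tau={self.tau}; need at least {(self.M - 1) * self.tau + 1}"
            )

    @property
    def K(self) -> int:
        """Number of state vectors, K = N - (M-1)·τ."""
        return self.N - (self.M - 1) * self.tau


@dataclass(frozen=True)
class DataMatrix:
    """K×M matrix of stacked state vectors (rows are states s_i)."""

    states: np.ndarray
    params: EmbeddingParams


def delay_embed(signal: np.ndarray, params: EmbeddingParams) -> DataMatrix:
    """Build the K×M data matrix; row i, column j holds ``signal[i + j*tau]``."""
    x = np.asarray(signal, dtype=float).ravel()
    if x.size != params.N:
        params = EmbeddingParams(params.tau, params.M, x.size)
    K = params.K
    idx = np.arange(K)[:, None] + params.tau * np.arange(params.M)[None, :]
    return DataMatrix(states=x[idx], params=params)


def embed(signal: np.ndarray, tau: int, M: int) -> DataMatrix:
    """Convenience wrapper: embed *signal* with lag ``tau`` and dimension ``M``."""
    x = np.asarray(signal, dtype=float).ravel()
    return delay_embed(x, EmbeddingParams(tau=tau, M=M, N=x.size))


def _mutual_information(x: np.ndarray, y: np.ndarray, bins: int = 16) -> float:
    h, _, _ = np.histogram2d(x, y, bins=bins)
    p = h / h.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def select_time_lag(signal: np.ndarray, method: str = "ami",
                    max_lag: int = 100) -> int:
    """Choose the embedding lag τ ∈ [1, max_lag].

    ``ami``      : first local minimum of the average mutual information
                   (the first lag followed by an increase).
    ``autocorr`` : first lag where the autocorrelation drops below 1/e.

    Falls back to ``max_lag`` with a warning when no minimum/crossing occurs.
    """
    x = np.asarray(signal, dtype=float).ravel()
    if x.size <= 2 * max_lag:
        raise ValueError(
            f"signal length {x.size} too short for max_lag={max_lag}"
        )
    if np.ptp(x) == 0:
        raise ValueError("constant signal has no meaningful time lag")
    if method == "autocorr":
        xc = x - x.mean()
        denom = float(xc @ xc)
        for lag in range(1, max_lag + 1):
            r = float(xc[:-lag] @ xc[lag:]) / denom
            if r < 1.0 / np.e:
                return lag
        warnings.warn("autocorrelation never crossed 1/e; returning max_lag")
        return max_lag
    if method == "ami":
        prev = _mutual_information(x[:-1], x[1:])
        for lag in range(1, max_lag):
            cur = _mutual_information(x[:-(lag + 1)], x[lag + 1:])
            if cur > prev:  # MI rose: previous lag was the first minimum
                return lag
            prev = cur
        warnings.warn("no AMI minimum found up to max_lag; returning max_lag")
        return max_lag
    raise ValueError(f"unknown method {method!r}")


def _cao_curves(x: np.ndarray, tau: int, m_max: int):
    """E1/E2 curves of Cao's method (Chebyshev norm, brute-force neighbours)."""
    N = x.size
    if N < m_max * tau + 2:
        raise ValueError(
            f"signal length {N} too short for m_max={m_max}, tau={tau}"
        )
    E = np.empty(m_max)
    Estar = np.empty(m_max)
    for m in range(1, m_max + 1):
        # Restrict to states whose (m+1)-dim extension exists.
        K = N - m * tau
        Y = embed(x[: K + (m - 1) * tau], tau, m).states
        d = cdist(Y, Y, metric="chebyshev")
        np.fill_diagonal(d, np.inf)
        d[d == 0] = np.inf  # Cao: nearest neighbour at nonzero distance
        nn = np.argmin(d, axis=1)
        dm = d[np.arange(K), nn]
        ext = np.abs(x[np.arange(K) + m * tau] - x[nn + m * tau])
        dm1 = np.maximum(dm, ext)  # Chebyshev distance in dimension m+1
        finite = np.isfinite(dm)
        E[m - 1] = float(np.mean(dm1[finite] / dm[finite]))
        Estar[m - 1] = float(np.mean(ext[finite]))
    E1 = E[1:] / E[:-1]
    E2 = Estar[1:] / Estar[:-1]
    return E1, E2


def cao_embedding_dimension(signal: np.ndarray, tau: int, m_max: int = 10,
                            e1_threshold: float = 0.2):
    """Minimum embedding dimension via Cao's method.

    Returns ``(M, E1, E2)`` where E1/E2 are the diagnostic curves over
    m = 1..m_max-1 (``E1[i]`` is E(m+1)/E(m) at m = i+1).  M is the smallest
    dimension from which E1 has saturated: the first m with
    ``E1(m') >= 1 - e1_threshold`` for every m' >= m.  The default threshold
    of 0.2 reflects that finite-sample E1 plateaus settle around 0.9 rather
    than exactly 1.  Falls back to m_max with a warning when E1 never
    saturates (typical for stochastic signals, for which E2 ≈ 1 at all m is
    the cleaner signature).
    """
    x = np.asarray(signal, dtype=float).ravel()
    E1, E2 = _cao_curves(x, int(tau), int(m_max))
    M = None
    for i in range(len(E1)):
        if np.min(E1[i:]) >= 1.0 - e1_threshold:
            M = i + 1  # index i corresponds to dimension m = i + 1
            break
    if M is None:
        warnings.warn("E1 did not saturate; returning m_max")
        M = m_max
    return M, E1, E2
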