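"""Recurrence quantification analysis.

Ten scalar measures are computed from the diagonal- and vertical-line
structures of a square binary recurrence grid:

=====  ==========================  ==================================================
F1     RR (recurrence rate)        (1/N²) Σ R[x,y]
F2     DET (determinism)           Σ_{len>=lmin} len·P(len) / Σ_{len>=1} len·P(len)
F3     avg diagonal length d̄_L    Σ_{len>=lmin} len·P(len) / Σ_{len>=lmin} P(len)
F4     d_Lmax                      longest diagonal line
F5     H (entropy)                 -Σ_{len>=lmin} p(len) ln p(len)
F6     LAM (laminarity)            Σ_{vl>=vmin} vl·P(vl) / Σ_{vl>=1} vl·P(vl)
F7     TT (trapping time)          Σ_{vl>=vmin} vl·P(vl) / Σ_{vl>=vmin} P(vl)
F8     V_max                       longest vertical line
F9     DIV (divergence)            1 / d_Lmax
F10    RDR                         N²·Σ_{len>=lmin} len·P(len) / (Σ_{len>=1} len·P(len))²
=====  ==========================  ==================================================

P(len)/P(vl) are the histograms of maximal diagonal/vertical run lengths.
With no Theiler exclusion, RDR equals DET/RR identically because the
diagonal runs partition the recurrence points.

Degenerate conventions: an empty histogram above the minimum length gives
DET = d̄_L = H = 0 (likewise LAM/TT); with no recurrence points at all every
ratio is 0; DIV is NaN when no diagonal line exists (1/0 sentinel).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Dict, Optional, Union

import numpy as np

from .recurrence import BinaryRP

#: Column order of the feature table (F1..F10).
FEATURE_NAMES = ("RR", "DET", "avg_diag", "d_Lmax", "entropy",
                 "LAM", "TT", "V_max", "DIV", "RDR")


@dataclass
class LineHistograms:
    """Counts of maximal diagonal / vertical line lengths."""

    diag: Dict[int, int]
    vert: Dict[int, int]
    N: int
    theiler: int = 0


@dataclass
class RQAFeatureVector:
    RR: float
    DET: float
    avg_diag: float
    d_Lmax: float
    entropy: float
    LAM: float
    TT: float
    V_max: float
    DIV: float
    RDR: float
    lmin: int = 2
    vmin: int = 2
    source: str = "full_rp"

    def as_dict(self) -> Dict[str, float]:
        return asdict(self)

    def values(self) -> np.ndarray:
        """The ten features as a vector in F1..F10 order."""
        d = asdict(self)
        return np.array([d[k] for k in FEATURE_NAMES], dtype=float)


def _as_grid(B: Union[BinaryRP, np.ndarray]) -> tuple[np.ndarray, int]:
    if isinstance(B, BinaryRP):
        return np.asarray(B.grid, dtype=np.uint8), B.theiler
    g = np.asarray(B)
    if g.ndim != 2 or g.shape[0] != g.shape[1]:
        raise ValueError("binary recurrence grid must be square")
    return (g != 0).astype(np.uint8), 0


def _run_lengths(line: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of ones in a 1-D 0/1 array."""
    if line.size == 0:
        return np.empty(0, dtype=int)
    padded = np.concatenate(([0], line, [0]))
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return ends - starts


def diagonal_line_histogram(B: Union[BinaryRP, np.ndarray],
                            theiler: Optional[int] = None) -> Dict[int, int]:
    """Histogram of maximal diagonal run lengths.

    Diagonals with offset |i-j| <= theiler are excluded (theiler defaults to
    the plot's own Theiler band, 0 for plain arrays).
    """
    grid, th = _as_grid(B)
    if theiler is not None:
        th = theiler
    N = grid.shape[0]
    hist: Dict[int, int] = {}
    for off in range(-(N - 1), N):
        if abs(off) <= th and th > 0:
            continue
        runs = _run_lengths(np.diagonal(grid, off))
        for r in runs:
            hist[int(r)] = hist.get(int(r), 0) + 1
    return hist


def vertical_line_histogram(B: Union[BinaryRP, np.ndarray],
                            theiler: Optional[int] = None) -> Dict[int, int]:
    """Histogram of maximal vertical run lengths per column.

    With a Theiler band, cells |i-j| <= theiler are removed before the runs
    are measured (consistent with the diagonal histogram).
    """
    grid, th = _as_grid(B)
    if theiler is not None:
        th = theiler
    if th > 0:
        grid = grid.copy()
        i, j = np.indices(grid.shape)
        grid[np.abs(i - j) <= th] = 0
    hist: Dict[int, int] = {}
    for col in grid.T:
        for r in _run_lengths(col):
            hist[int(r)] = hist.get(int(r), 0) + 1
    return hist


def line_histograms(B: Union[BinaryRP, np.ndarray]) -> LineHistograms:
    grid, th = _as_grid(B)
    return LineHistograms(diag=diagonal_line_histogram(B),
                          vert=vertical_line_histogram(B),
                          N=grid.shape[0], theiler=th)


def _hist_sums(hist: Dict[int, int], minlen: int):
    total = sum(l * c for l, c in hist.items())          # over len >= 1
    sel = {l: c for l, c in hist.items() if l >= minlen}
    sel_pts = sum(l * c for l, c in sel.items())
    sel_lines = sum(sel.values())
    return total, sel_pts, sel_lines, sel


def rqa_features(B: Union[BinaryRP, np.ndarray], lmin: int = 2,
                 vmin: int = 2, source: str = "full_rp") -> RQAFeatureVector:
    """Compute the ten RQA features of a square binary grid."""
    if lmin < 1 or vmin < 1:
        raise ValueError("lmin and vmin must be >= 1")
    grid, th = _as_grid(B)
    N = grid.shape[0]
    n_points = int(grid.sum())
    RR = n_points / N**2
    dh = diagonal_line_histogram(B)
    vh = vertical_line_histogram(B)

    d_total, d_sel_pts, d_sel_lines, d_sel = _hist_sums(dh, lmin)
    DET = d_sel_pts / d_total if d_total else 0.0
    avg_diag = d_sel_pts / d_sel_lines if d_sel_lines else 0.0
    d_Lmax = float(max(dh)) if dh else 0.0
    if d_sel_lines:
        p = np.array(list(d_sel.values()), dtype=float) / d_sel_lines
        entropy = float(-(p * np.log(p)).sum())
    else:
        entropy = 0.0

    v_total, v_sel_pts, v_sel_lines, _ = _hist_sums(vh, vmin)
    LAM = v_sel_pts / v_total if v_total else 0.0
    TT = v_sel_pts / v_sel_lines if v_sel_lines else 0.0
    V_max = float(max(vh)) if vh else 0.0

    DIV = 1.0 / d_Lmax if d_Lmax > 0 else float("nan")
    RDR = N**2 * d_sel_pts / d_total**2 if d_total else 0.0

    return RQAFeatureVector(RR=RR, DET=DET, avg_diag=avg_diag, d_Lmax=d_Lmax,
                            entropy=entropy, LAM=LAM, TT=TT, V_max=V_max,
                            DIV=DIV, RDR=RDR, lmin=lmin, vmin=vmin,
                            source=source)


def binarize_latent(latent: np.ndarray, policy: str = "otsu",
                    value: float = 0.2) -> np.ndarray:
    """Binarise a real-valued latent grid.

    ``otsu`` (default) thresholds the min-max normalised grid with Otsu's
    method, adapting to the grid's own amplitude structure so the
    recurrence rate stays informative; ``quantile`` marks the top-``value``
    fraction of cells as recurrent (ties included, so a constant grid
    becomes all ones), pinning the recurrence rate at ``value``.
    """
    g = np.asarray(latent, dtype=float)
    lo, hi = g.min(), g.max()
    norm = np.zeros_like(g) if hi == lo else (g - lo) / (hi - lo)
    if policy == "quantile":
        if not 0.0 < value < 1.0:
            raise ValueError("quantile value must lie in (0, 1)")
        thr = np.quantile(norm, 1.0 - value)
        return (norm >= thr).astype(np.uint8)
    if policy == "otsu":
        from skimage.filters import threshold_otsu
        if hi == lo:
            return np.ones_like(norm, dtype=np.uint8)
        return (norm > threshold_otsu(norm)).astype(np.uint8)
    raise ValueError(f"unknown policy {policy!r}")


def latent_rqa(latent: np.ndarray, binarize_policy: str = "otsu",
               value: float = 0.2, lmin: int = 2,
               vmin: int = 2) -> RQAFeatureVector:
    """RQA features of a real-valued latent embedding.

    The latent grid is min-max normalised, binarised (quantile policy by
    default), and treated as a recurrence-like grid.
    """
    grid = binarize_latent(latent, binarize_policy, value)
    return rqa_features(grid, lmin=lmin, vmin=vmin, source="latent")


class RQAFeaturizer:
    """Map an array of latent grids (n, h, w) to an (n, 10) feature matrix.

    sklearn-style transformer (stateless); ``feature_names_out_`` follows
    :data:`FEATURE_NAMES`.
    """

    def __init__(self, binarize_policy: str = "otsu", value: float = 0.2,
                 lmin: int = 2, vmin: int = 2):
        self.binarize_policy = binarize_policy
        self.value = value
        self.lmin = lmin
        self.vmin = vmin

    def get_params(self, deep: bool = True):
        return {"binarize_policy": self.binarize_policy, "value": self.value,
                "lmin": self.lmin, "vmin": self.vmin}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        self.feature_names_out_ = list(FEATURE_NAMES)
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        rows = [latent_rqa(g, self.binarize_policy, self.value,
                           self.lmin, self.vmin).values() for g in X]
        return np.asarray(rows)

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
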