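"""Independent brute-force reference implementations used only by tests.

Each oracle is written directly from first principles (plain loops,
itertools), deliberately sharing no code with the package implementation.
"""

from itertools import combinations, groupby

import numpy as np


# -- RQA -------------------------------------------------------------------

def runs_in_line(line):
    """Lengths of maximal runs of ones via groupby."""
    return [len(list(g)) for v, g in groupby(line) if v]


def diag_hist_bf(grid, theiler=0):
    n = grid.shape[0]
    hist = {}
    for off in range(-(n - 1), n):
        if theiler > 0 and abs(off) <= theiler:
            continue
        line = [grid[i, i + off] for i in range(n)
                if 0 <= i + off < n]
        for r in runs_in_line(line):
            hist[r] = hist.get(r, 0) + 1
    return hist


def vert_hist_bf(grid, theiler=0):
    n = grid.shape[0]
    hist = {}
    for j in range(n):
        col = [0 if (theiler > 0 and abs(i - j) <= theiler) else grid[i, j]
               for i in range(n)]
        for r in runs_in_line(col):
            hist[r] = hist.get(r, 0) + 1
    return hist


def rqa_bf(grid, lmin=2, vmin=2):
    """All ten RQA features by direct transcription of their formulas."""
    grid = np.asarray(grid)
    n = grid.shape[0]
    dh = diag_hist_bf(grid)
    vh = vert_hist_bf(grid)
    npts = int(grid.sum())
    rr = npts / n**2
    d_all = sum(l * c for l, c in dh.items())
    d_sel = sum(l * c for l, c in dh.items() if l >= lmin)
    d_lines = sum(c for l, c in dh.items() if l >= lmin)
    det = d_sel / d_all if d_all else 0.0
    avg = d_sel / d_lines if d_lines else 0.0
    dmax = max(dh) if dh else 0.0
    if d_lines:
        ent = 0.0
        for l, c in dh.items():
            if l >= lmin:
                p = c / d_lines
                ent -= p * np.log(p)
    else:
        ent = 0.0
    v_all = sum(l * c for l, c in vh.items())
    v_sel = sum(l * c for l, c in vh.items() if l >= vmin)
    v_lines = sum(c for l, c in vh.items() if l >= vmin)
    lam = v_sel / v_all if v_all else 0.0
    tt = v_sel / v_lines if v_lines else 0.0
    vmax = max(vh) if vh else 0.0
    div = 1.0 / dmax if dmax else float("nan")
    rdr = n**2 * d_sel / d_all**2 if d_all else 0.0
    return {"RR": rr, "DET": det, "avg_diag": avg, "d_Lmax": float(dmax),
            "entropy": ent, "LAM": lam, "TT": tt, "V_max": float(vmax),
            "DIV": div, "RDR": rdr}


# -- distances -------------------------------------------------------------

def distance_matrix_bf(states):
    k = len(states)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            out[i, j] = np.sqrt(sum((a - b) ** 2
                                    for a, b in zip(states[i], states[j])))
    return out


# -- Cao's method ----------------------------------------------------------

def cao_curves_bf(x, tau, m_max):
    """E1/E2 by explicit loops: Chebyshev nearest neighbours per dimension."""
    x = np.asarray(x, float)
    N = len(x)
    E = []
    Estar = []
    for m in range(1, m_max + 1):
        K = N - m * tau
        vecs = [x[i:i + m * tau:tau] for i in range(K)]
        a_vals, ext_vals = [], []
        for i in range(K):
            best, best_j = np.inf, -1
            for j in range(K):
                if j == i:
                    continue
                d = max(abs(a - b) for a, b in zip(vecs[i], vecs[j]))
                if 0 < d < best:
                    best, best_j = d, j
            if not np.isfinite(best):
                continue
            d_next = max(best, abs(x[i + m * tau] - x[best_j + m * tau]))
            a_vals.append(d_next / best)
            ext_vals.append(abs(x[i + m * tau] - x[best_j + m * tau]))
        E.append(np.mean(a_vals))
        Estar.append(np.mean([abs(x[i + m * tau] - x[j + m * tau])
                              for i, j in nn_pairs(vecs, x, m, tau)]))
    E = np.asarray(E)
    Estar = np.asarray(Estar)
    return E[1:] / E[:-1], Estar[1:] / Estar[:-1]


def nn_pairs(vecs, x, m, tau):
    """(i, nearest-neighbour) index pairs at nonzero Chebyshev distance."""
    out = []
    for i in range(len(vecs)):
        best, best_j = np.inf, -1
        for j in range(len(vecs)):
            if j == i:
                continue
            d = max(abs(a - b) for a, b in zip(vecs[i], vecs[j]))
            if 0 < d < best:
                best, best_j = d, j
        if best_j >= 0:
            out.append((i, best_j))
    return out


# -- rank-sum --------------------------------------------------------------

def ranksum_exact_bf(a, b):
    """Exact two-sided p by enumerating every group assignment of ranks."""
    a, b = list(a), list(b)
    pooled = np.asarray(a + b, float)
    n, n1 = len(pooled), len(a)
    order = pooled.argsort(kind="stable")
    ranks = np.empty(n)
    # midranks
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    obs = ranks[:n1].sum()
    mid = n1 * (n + 1) / 2.0
    dev = abs(obs - mid)
    extreme = total = 0
    for idx in combinations(range(n), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mid) >= dev - 1e-12:
            extreme += 1
    return extreme / total


# -- confusion matrix ------------------------------------------------------

def confusion_bf(pred, truth, order):
    k = len(order)
    pos = {c: i for i, c in enumerate(order)}
    cm = np.zeros((k, k), dtype=int)
    for p, t in zip(pred, truth):
        cm[pos[t], pos[p]] += 1
    return cm
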