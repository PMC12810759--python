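"""Wilcoxon rank-sum (Mann-Whitney) screening of RQA features.

Feature screening compares each RQA feature between every unordered pair of
study groups with a two-sided rank-sum test at α = 0.05 (no multiplicity
correction by default, matching raw p < 0.05 reporting; Holm adjustment is
available behind a flag).

The exact null distribution of the U statistic is computed in-package with
the standard count recurrence (ties fall back to enumerating rank
assignments); the normal approximation delegates to scipy's asymptotic
Mann-Whitney implementation (continuity and tie corrected).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from math import comb
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata


@dataclass
class StatTestResult:
    feature: str
    group_a: str
    group_b: str
    statistic: float  # Mann-Whitney U of the first group
    p_value: float
    significant: bool
    alpha: float = 0.05


@lru_cache(maxsize=None)
def _u_null_counts(n1: int, n2: int) -> np.ndarray:
    """Frequencies of U = 0..n1*n2 under the no-tie null.

    Count (shift) recurrence N(u; m, n) = N(u-n; m-1, n) + N(u; m, n-1)
    with N(u; 0, n) = N(u; m, 0) = [u == 0]; the total over u is
    C(n1+n2, n1).
    """
    size = n1 * n2 + 1
    prev_row = [np.zeros(size) for _ in range(n2 + 1)]  # m = 0
    for arr in prev_row:
        arr[0] = 1.0
    for m in range(1, n1 + 1):
        row = [np.zeros(size) for _ in range(n2 + 1)]
        row[0][0] = 1.0
        for n in range(1, n2 + 1):
            shifted = np.zeros(size)
            shifted[n:] = prev_row[n][: size - n]
            row[n] = shifted + row[n - 1]
        prev_row = row
    counts = prev_row[n2]
    assert counts.sum() == comb(n1 + n2, n1)
    return counts


def _exact_p_no_ties(u: float, n1: int, n2: int) -> float:
    counts = _u_null_counts(n1, n2)
    total = counts.sum()
    mid = n1 * n2 / 2.0
    dev = abs(u - mid)
    support = np.arange(n1 * n2 + 1)
    extreme = counts[np.abs(support - mid) >= dev - 1e-12].sum()
    return min(1.0, float(extreme / total))


def _exact_p_enumerate(pooled: np.ndarray, n1: int) -> Tuple[float, float]:
    """Exact two-sided p by enumerating group assignments (handles ties)."""
    n = len(pooled)
    ranks = rankdata(pooled)
    obs_r = ranks[:n1].sum()
    mid = n1 * (n + 1) / 2.0
    dev = abs(obs_r - mid)
    extreme = total = 0
    for idx in combinations(range(n), n1):
        total += 1
        r = ranks[list(idx)].sum()
        if abs(r - mid) >= dev - 1e-12:
            extreme += 1
    u = obs_r - n1 * (n1 + 1) / 2.0
    return u, extreme / total


def ranksum_test(a: Sequence[float], b: Sequence[float],
                 mode: str = "exact") -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns ``(U_a, p)``.

    ``exact`` computes the exact two-sided p (null distribution of U via
    the count recurrence; with ties, by enumerating the C(n, n_a) group
    assignments — feasible for the small per-group samples screening uses).
    ``normal_approx`` applies the continuity- and tie-corrected normal
    approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if mode == "normal_approx":
        res = mannwhitneyu(a, b, alternative="two-sided",
                           method="asymptotic", use_continuity=True)
        return float(res.statistic), float(res.pvalue)
    if mode != "exact":
        raise ValueError(f"unknown mode {mode!r}")
    pooled = np.concatenate([a, b])
    if pooled.size > 25:
        raise ValueError(
            f"exact mode supports combined n <= 25, got {pooled.size}; "
            "use mode='normal_approx'"
        )
    ranks = rankdata(pooled)
    u = float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0)
    if len(np.unique(pooled)) == pooled.size:  # no ties
        return u, _exact_p_no_ties(u, a.size, b.size)
    u, p = _exact_p_enumerate(pooled, a.size)
    return float(u), float(p)


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


def screen_features(features: pd.DataFrame, group_col: str = "label",
                    alpha: float = 0.05, mode: str = "auto",
                    holm: bool = False,
                    feature_cols: Sequence[str] | None = None,
                    ) -> List[StatTestResult]:
    """Pairwise rank-sum screening of every feature across group pairs.

    ``features`` holds one row per record: feature columns plus a group
    column.  Every (feature, unordered group pair) is tested; significance
    is judged at raw ``alpha`` (Holm-adjusted when ``holm=True``).
    ``mode='auto'`` uses the exact test when the combined sample is small
    enough (<= 25) and the normal approximation otherwise.
    """
    if group_col not in features.columns:
        raise ValueError(f"missing group column {group_col!r}")
    groups = sorted(features[group_col].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if (features[group_col] == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    if feature_cols is None:
        feature_cols = [c for c in features.columns
                        if c != group_col
                        and np.issubdtype(features[c].dtype, np.number)]
    results: List[StatTestResult] = []
    for feat in feature_cols:
        for ga, gb in combinations(groups, 2):
            a = features.loc[features[group_col] == ga, feat].to_numpy(float)
            b = features.loc[features[group_col] == gb, feat].to_numpy(float)
            a, b = a[~np.isnan(a)], b[~np.isnan(b)]
            if a.size < 2 or b.size < 2:
                continue
            m = mode
            if m == "auto":
                m = "exact" if a.size + b.size <= 25 else "normal_approx"
            stat, p = ranksum_test(a, b, mode=m)
            results.append(StatTestResult(feat, str(ga), str(gb), stat, p,
                                          p < alpha, alpha))
    if holm and results:
        adj = _holm(np.array([r.p_value for r in results]))
        for r, q in zip(results, adj):
            r.p_value = float(q)
            r.significant = q < alpha
    return results


def screen_to_frame(results: Sequence[StatTestResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "feature": r.feature, "group_a": r.group_a, "group_b": r.group_b,
        "statistic": r.statistic, "p_value": r.p_value,
        "significant": r.significant,
    } for r in results])


def significant_summary(results: Sequence[StatTestResult]
                        ) -> Dict[str, int]:
    """Counts at both granularities: distinct features and (feature, pair) hits."""
    sig = [r for r in results if r.significant]
    return {"n_significant_pairs": len(sig),
            "n_significant_features": len({r.feature for r in sig})}
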