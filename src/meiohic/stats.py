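"""Shared statistical helpers: rank-sum wrapper and BH step-up."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["rank_sum_test", "bh_adjust"]

EXACT_MAX_N = 12  # exact null enumeration up to this group size
_PERM_RESAMPLES = 10_000  # midrank permutation null for tied data
_PERM_SEED = 19_680_424  # fixed: the test is deterministic


def rank_sum_test(x, y) -> tuple[float, float, int]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null enumeration for untied group sizes up to 12; a midrank
    permutation null (10,000 resamples, fixed seed) when ties are present —
    the normal approximation is anti-conservative on heavily tied count
    data; normal approximation with continuity correction otherwise.
    Returns ``(statistic, p, direction)`` with direction +1 when ``x``
    tends larger, -1 when smaller, 0 on exact ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    mid = nx * ny / 2.0
    if has_ties:
        ranks = sps.rankdata(pooled)
        obs = ranks[:nx].sum()
        expect = nx * (nx + ny + 1) / 2.0
        rng = np.random.default_rng(_PERM_SEED)
        order = np.argsort(rng.random((_PERM_RESAMPLES, nx + ny)), axis=1)
        null = ranks[order[:, :nx]].sum(axis=1)
        p = (1 + np.sum(np.abs(null - expect) >= np.abs(obs - expect) - 1e-12)) / (
            _PERM_RESAMPLES + 1
        )
        u = obs - nx * (nx + 1) / 2.0
        return float(u), float(min(p, 1.0)), int(np.sign(u - mid))
    method = "exact" if nx <= EXACT_MAX_N and ny <= EXACT_MAX_N else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    direction = int(np.sign(res.statistic - mid))
    return float(res.statistic), float(res.pvalue), direction


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, never below p)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
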