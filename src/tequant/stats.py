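"""Shared statistical primitives: Mann–Whitney U and BH-FDR.

The Mann–Whitney implementation enumerates the exact permutation null
(ties handled naturally) when both groups hold at most ``exact_limit``
values, and otherwise uses the normal approximation with tie correction
and a 0.5 continuity correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

EXACT_LIMIT = 8


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float  # U for the first sample
    p_value: float
    method: str  # "exact" or "normal"


def _u_from_ranks(rank_sum1: float, n1: int) -> float:
    return rank_sum1 - n1 * (n1 + 1) / 2.0


def mann_whitney_u(x, y, exact_limit: int = EXACT_LIMIT) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test of ``x`` vs ``y``.

    Exact enumeration over all C(n1+n2, n1) group assignments when both
    groups have at most ``exact_limit`` observations; otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = _u_from_ranks(ranks[:n1].sum(), n1)
    mu = n1 * n2 / 2.0

    if n1 <= exact_limit and n2 <= exact_limit:
        # enumerate every split of the pooled ranks into a group of n1
        d_obs = abs(u_obs - mu)
        n_total = n1 + n2
        hits = 0
        total = 0
        for combo in itertools.combinations(range(n_total), n1):
            u = _u_from_ranks(ranks[list(combo)].sum(), n1)
            if abs(u - mu) >= d_obs - 1e-12:
                hits += 1
            total += 1
        return MannWhitneyResult(u_obs, hits / total, "exact")

    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return MannWhitneyResult(u_obs, 1.0, "normal")
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * sps.norm.sf(z))
    return MannWhitneyResult(u_obs, p, "normal")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, ≤ 1)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out
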