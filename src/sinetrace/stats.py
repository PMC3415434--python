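"""Rank statistics shared by the A-tail and window-enrichment analyses.

The Mann-Whitney U implementation is deliberately self-contained: exact
enumeration over all labelings for small pooled samples (handles ties by
construction) and a tie-corrected normal approximation with continuity
correction otherwise.  Tests cross-check it against scipy and against an
exhaustive permutation oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
from scipy.stats import rankdata, norm

Alternative = Literal["two-sided", "less", "greater"]

__all__ = ["MannWhitneyResult", "mann_whitney_u", "u_statistic"]


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float          # U statistic for the first sample
    z: float          # tie-corrected normal deviate (continuity-corrected)
    p: float
    method: str       # "exact" or "asymptotic"


def u_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    """U for ``x`` via midrank sums: U = R_x - n_x(n_x+1)/2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ranks = rankdata(np.concatenate([x, y]))
    return float(ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2)


def _normal_z(u: float, x: np.ndarray, y: np.ndarray) -> float:
    n1, n2 = len(x), len(y)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    if var <= 0:
        return 0.0
    d = u - mu
    # continuity correction toward the mean
    if d > 0.5:
        d -= 0.5
    elif d < -0.5:
        d += 0.5
    else:
        d = 0.0
    return d / math.sqrt(var)


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: Alternative = "two-sided",
    exact_max_n: int = 10,
) -> MannWhitneyResult:
    """Mann-Whitney U test of ``x`` vs ``y``.

    For pooled sizes up to ``exact_max_n`` the p-value is computed by
    enumerating every C(n1+n2, n1) assignment of the pooled values to the two
    groups (exact even under ties); otherwise a tie-corrected normal
    approximation with continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    u_obs = u_statistic(x, y)
    mu = n1 * n2 / 2.0
    z = _normal_z(u_obs, x, y)

    if n1 + n2 <= exact_max_n:
        pooled = np.concatenate([x, y])
        ranks = rankdata(pooled)
        offset = n1 * (n1 + 1) / 2
        us = np.array(
            [ranks[list(idx)].sum() - offset for idx in combinations(range(n1 + n2), n1)]
        )
        if alternative == "greater":
            p = float(np.mean(us >= u_obs - 1e-9))
        elif alternative == "less":
            p = float(np.mean(us <= u_obs + 1e-9))
        else:
            p = float(np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-9))
        return MannWhitneyResult(u=u_obs, z=z, p=min(p, 1.0), method="exact")

    if alternative == "greater":
        p = float(norm.sf(z))
    elif alternative == "less":
        p = float(norm.cdf(z))
    else:
        p = float(2.0 * norm.sf(abs(z)))
    return MannWhitneyResult(u=u_obs, z=z, p=min(p, 1.0), method="asymptotic")
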