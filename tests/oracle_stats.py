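"""Brute-force rank-statistic oracles, independent of the package's code.

Ranks are computed by direct counting (number smaller + half the ties),
never via scipy; formulas are written out from their definitions. Only
meant for tiny inputs in tests.
"""

from __future__ import annotations

import math
from itertools import combinations


def brute_ranks(pooled: list[float]) -> list[float]:
    """Mid-ranks by counting: rank(v) = #(smaller) + (#(equal) + 1) / 2."""
    ranks = []
    for v in pooled:
        smaller = sum(1 for u in pooled if u < v)
        equal = sum(1 for u in pooled if u == v)
        ranks.append(smaller + (equal + 1) / 2)
    return ranks


def _tie_term(pooled: list[float]) -> float:
    return sum(
        count**3 - count for count in (pooled.count(v) for v in set(pooled))
    )


def brute_kruskal_h(groups: list[list[float]]) -> float:
    """Tie-corrected Kruskal-Wallis H from first principles."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = brute_ranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        mean_rank = sum(ranks[start : start + len(g)]) / len(g)
        h += len(g) * (mean_rank - (n + 1) / 2) ** 2
        start += len(g)
    h *= 12.0 / (n * (n + 1))
    correction = 1.0 - _tie_term(pooled) / (n**3 - n)
    if correction == 0:
        return 0.0
    return h / correction


def brute_dunn(groups: list[list[float]]) -> list[tuple[int, int, float, float]]:
    """Dunn pairwise (i, j, z, two-sided p) from pooled mid-ranks."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = brute_ranks(pooled)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(sum(ranks[start : start + len(g)]) / len(g))
        start += len(g)
    base_var = n * (n + 1) / 12.0 - _tie_term(pooled) / (12.0 * (n - 1))
    out = []
    for i, j in combinations(range(len(groups)), 2):
        var = base_var * (1.0 / len(groups[i]) + 1.0 / len(groups[j]))
        z = 0.0 if var <= 0 else (mean_ranks[i] - mean_ranks[j]) / math.sqrt(var)
        p = 2.0 * (1.0 - _normal_cdf(abs(z)))
        out.append((i, j, z, p))
    return out


def brute_welch(x: list[float], y: list[float]) -> tuple[float, float]:
    """Welch t statistic and Welch-Satterthwaite df by direct arithmetic."""
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, df


def _normal_cdf(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))
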