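"""Per-frequency group statistics on the band-power features.

Two comparison schemes mirror the target analysis:

* ``pain-binary`` — pain(-) (NRS 0) vs pain(+) (NRS >= 1), one Welch
  (unequal-variance) t-test per integer frequency 1-35 Hz;
* ``quartiles`` — the four pain levels, per frequency: Kruskal-Wallis
  omnibus followed by Dunn's pairwise z-tests on pooled ranks (six
  pairs).

Raw p-values are Bonferroni-corrected within each contrast family of 35
frequencies (a ``strict_pairs`` mode additionally multiplies Dunn p's by
the 6 pairs). In the default *protected* mode a Dunn pair at a given
frequency is called significant only when its Kruskal-Wallis omnibus is
also significant; all 6 x 35 rows are emitted either way, with the
omnibus p alongside.

Welch's t and Kruskal-Wallis delegate to scipy.stats; Dunn's test is
implemented here (pooled mid-ranks, tie correction) because no
pre-installed package provides it, and is cross-checked against a
brute-force rank oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import StatsError
from .pain import CLASS_ORDER
from .spectral import FEATURE_COLUMNS, FeatureDataset

__all__ = [
    "WelchResult",
    "DunnResult",
    "FrequencyComparison",
    "welch_t_test",
    "kruskal_wallis",
    "dunn_posthoc",
    "bonferroni",
    "per_frequency_comparison",
]


class WelchResult(NamedTuple):
    statistic: float
    df: float
    p_value: float


class DunnResult(NamedTuple):
    group_i: int
    group_j: int
    z: float
    p_value: float


@dataclass
class FrequencyComparison:
    """One frequency x one group contrast."""

    contrast: str
    frequency_hz: int
    test: str
    statistic: float
    df: float | None
    p_raw: float
    p_corrected: float
    significant: bool
    omnibus_p: float | None = None


def _as_sample(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise StatsError(f"sample {name} contains non-finite values")
    return x


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Two-sided unequal-variance t-test with Welch-Satterthwaite df."""
    x, y = _as_sample(x, "x"), _as_sample(y, "y")
    if len(x) < 2 or len(y) < 2:
        raise StatsError(f"Welch t-test needs >= 2 values per sample, got {len(x)} and {len(y)}")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return WelchResult(0.0, float(len(x) + len(y) - 2), 1.0)
        raise StatsError("both samples have zero variance with unequal means")
    res = sstats.ttest_ind(x, y, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p on k-1 df.

    Degenerate input where every pooled value is identical returns
    H = 0, p = 1 (the tie-correction convention: no rank variation means
    no evidence of any group difference).
    """
    arrays = [_as_sample(g, f"group {i}") for i, g in enumerate(groups)]
    if len(arrays) < 2:
        raise StatsError(f"Kruskal-Wallis needs >= 2 groups, got {len(arrays)}")
    for i, g in enumerate(arrays):
        if len(g) == 0:
            raise StatsError(f"group {i} is empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sstats.kruskal(*arrays)
    return float(h), float(p)


def dunn_posthoc(groups: Sequence[Sequence[float]]) -> list[DunnResult]:
    """Dunn's pairwise post-hoc z-tests on pooled mid-ranks.

    For groups i, j with sizes n_i, n_j, pooled size N, mean ranks
    Rbar_i, and tie term T = sum(t^3 - t) over tied values:

        z_ij = (Rbar_i - Rbar_j) /
               sqrt([N(N+1)/12 - T/(12(N-1))] (1/n_i + 1/n_j))

    Two-sided normal p per pair; p-values are raw (correction is the
    caller's concern). k groups produce C(k, 2) results in (i, j) order.
    """
    arrays = [_as_sample(g, f"group {i}") for i, g in enumerate(groups)]
    if len(arrays) < 2:
        raise StatsError(f"Dunn's test needs >= 2 groups, got {len(arrays)}")
    for i, g in enumerate(arrays):
        if len(g) == 0:
            raise StatsError(f"group {i} is empty")
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = sstats.rankdata(pooled)
    sizes = [len(g) for g in arrays]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(arrays))]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    base_var = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        base_var -= tie_term / (12.0 * (n_total - 1))
    results: list[DunnResult] = []
    for i, j in combinations(range(len(arrays)), 2):
        var = base_var * (1.0 / sizes[i] + 1.0 / sizes[j])
        if var <= 0:
            z = 0.0  # all values tied: no rank separation possible
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var)
        p = float(2.0 * sstats.norm.sf(abs(z)))
        results.append(DunnResult(i, j, float(z), p))
    return results


def bonferroni(p_values: Sequence[float], family_size: int | None = None) -> np.ndarray:
    """Multiply each p by the family size, capping at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise StatsError("p-values must lie in [0, 1]")
    m = len(p) if family_size is None else int(family_size)
    if m < len(p):
        raise StatsError(f"family_size {m} smaller than the number of p-values {len(p)}")
    return np.minimum(p * m, 1.0)


def _session_mean_frame(dataset: FeatureDataset) -> pd.DataFrame:
    frame = dataset.frame
    grouped = frame.groupby(["subject_id", "phase"], sort=True)
    out = grouped[FEATURE_COLUMNS].mean()
    out["quartile"] = grouped["quartile"].first()
    out["nrs"] = grouped["nrs"].first()
    return out.reset_index()


def per_frequency_comparison(
    dataset: FeatureDataset,
    scheme: str = "pain-binary",
    alpha: float = 0.05,
    family_size: int | None = None,
    protected: bool = True,
    strict_pairs: bool = False,
    unit: str = "window",
) -> pd.DataFrame:
    """Compare feature distributions between pain groups at every frequency.

    Parameters
    ----------
    scheme
        ``"pain-binary"``: one Welch t-test per frequency, pain(+) minus
        pain(-). ``"quartiles"``: per frequency, Kruskal-Wallis omnibus
        then all six Dunn pairs.
    alpha
        Significance level applied to corrected p-values.
    family_size
        Bonferroni family; default 35 (frequencies per contrast).
    protected
        Quartile scheme only: require the omnibus p < alpha before a
        pair may be significant (rows are emitted regardless).
    strict_pairs
        Quartile scheme only: additionally multiply Dunn p's by the 6
        pairs (family 210).
    unit
        ``"window"`` (default, one row per 30-s window) or ``"session"``
        (features averaged per session first, 46 units by default).

    Returns a DataFrame with columns contrast, frequency_hz, test,
    statistic, df, p_raw, p_corrected, significant (plus omnibus_p for
    the quartile scheme), sorted by contrast then frequency.
    """
    if unit not in ("window", "session"):
        raise StatsError(f"unit must be 'window' or 'session', got {unit!r}")
    frame = dataset.frame if unit == "window" else _session_mean_frame(dataset)
    m = 35 if family_size is None else int(family_size)
    rows: list[FrequencyComparison] = []

    if scheme == "pain-binary":
        mask_plus = frame["quartile"] != "none"
        if mask_plus.all() or (~mask_plus).all():
            raise StatsError("pain-binary scheme needs both pain(+) and pain(-) rows")
        for f, column in enumerate(FEATURE_COLUMNS, start=1):
            res = welch_t_test(frame.loc[mask_plus, column], frame.loc[~mask_plus, column])
            p_corr = float(bonferroni([res.p_value], m)[0])
            rows.append(
                FrequencyComparison(
                    contrast="pain+ vs pain-",
                    frequency_hz=f,
                    test="welch-t",
                    statistic=res.statistic,
                    df=res.df,
                    p_raw=res.p_value,
                    p_corrected=p_corr,
                    significant=p_corr < alpha,
                )
            )
    elif scheme == "quartiles":
        present = [q for q in CLASS_ORDER if (frame["quartile"] == q).any()]
        if len(present) < 2:
            raise StatsError("quartile scheme needs >= 2 populated pain levels")
        groups_by_level = {q: frame[frame["quartile"] == q] for q in present}
        pair_family = m * 6 if strict_pairs else m
        for f, column in enumerate(FEATURE_COLUMNS, start=1):
            samples = [groups_by_level[q][column].to_numpy() for q in present]
            _, kw_p = kruskal_wallis(samples)
            for pair in dunn_posthoc(samples):
                p_corr = float(bonferroni([pair.p_value], pair_family)[0])
                significant = p_corr < alpha
                if protected:
                    significant = significant and kw_p < alpha
                rows.append(
                    FrequencyComparison(
                        contrast=f"{present[pair.group_i]} vs {present[pair.group_j]}",
                        frequency_hz=f,
                        test="dunn",
                        statistic=pair.z,
                        df=None,
                        p_raw=pair.p_value,
                        p_corrected=p_corr,
                        significant=significant,
                        omnibus_p=kw_p,
                    )
                )
    else:
        raise StatsError(f"unknown scheme {scheme!r}; use 'pain-binary' or 'quartiles'")

    out = pd.DataFrame([vars(r) for r in rows])
    out = out.sort_values(["contrast", "frequency_hz"], kind="stable").reset_index(drop=True)
    return out
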