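"""Group compliance comparison: Kruskal–Wallis omnibus + Dunn post hoc.

Wear-time distributions across recruited groups are skewed, have unequal
variances and very different sample sizes, so group differences in
compliance (each subject's study-average daily wear fraction, one number
per subject) are tested with the rank-based Kruskal–Wallis H test; when
the omnibus is significant, Dunn's z statistics give the pairwise
contrasts. Dunn p-values are reported both raw and Holm-adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class GroupComparisonResult:
    """Omnibus H/p plus pairwise Dunn matrices.

    ``z`` is antisymmetric (z_ij = -z_ji, rows minus columns in mean
    rank); ``p_raw`` and ``p_holm`` are symmetric; ``significant`` flags
    Holm-adjusted p below ``alpha``.
    """

    h: float
    p_omnibus: float
    group_names: tuple[str, ...]
    z: pd.DataFrame
    p_raw: pd.DataFrame
    p_holm: pd.DataFrame
    significant: pd.DataFrame
    alpha: float


def _validate_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    out = {}
    for name, values in groups.items():
        x = np.asarray(values, dtype=float)
        if x.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 subjects")
        if not np.isfinite(x).all():
            raise ValueError(f"group {name!r} contains non-finite values")
        out[str(name)] = x
    return out


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) and chi-squared p on k-1 df.

    When every observation is identical the statistic degenerates to
    H = 0, p = 1 (no evidence of any difference).
    """
    g = _validate_groups(groups)
    pooled = np.concatenate(list(g.values()))
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*g.values())
    return float(h), float(p)


def dunn_posthoc(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> GroupComparisonResult:
    """Dunn's pairwise rank test with tie correction and Holm adjustment.

    z_ij = (mean rank_i - mean rank_j) / sqrt(S * (1/n_i + 1/n_j)) where
    S = N(N+1)/12 - sum(t^3 - t)/(12(N-1)) over tie groups of size t;
    two-sided p from the standard normal.
    """
    g = _validate_groups(groups)
    names = tuple(g)
    h, p_omni = kruskal_wallis(groups)

    sizes = {k: v.size for k, v in g.items()}
    pooled = np.concatenate([g[k] for k in names])
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    mean_rank: dict[str, float] = {}
    start = 0
    for k in names:
        mean_rank[k] = float(ranks[start : start + sizes[k]].mean())
        start += sizes[k]

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n_total - 1)))
    s2 = n_total * (n_total + 1) / 12.0 - tie_term

    k = len(names)
    z = np.zeros((k, k))
    p = np.ones((k, k))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i == j:
                continue
            denom = np.sqrt(s2 * (1.0 / sizes[a] + 1.0 / sizes[b]))
            zij = 0.0 if denom == 0 else (mean_rank[a] - mean_rank[b]) / denom
            z[i, j] = zij
            p[i, j] = 2.0 * sps.norm.sf(abs(zij))

    iu = np.triu_indices(k, 1)
    raw_upper = p[iu]
    holm_upper = multipletests(raw_upper, method="holm")[1] if len(raw_upper) else raw_upper
    p_holm = np.ones((k, k))
    p_holm[iu] = holm_upper
    p_holm[(iu[1], iu[0])] = holm_upper

    def frame(m: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(m, index=list(names), columns=list(names))

    return GroupComparisonResult(
        h=h,
        p_omnibus=p_omni,
        group_names=names,
        z=frame(z),
        p_raw=frame(p),
        p_holm=frame(p_holm),
        significant=frame(p_holm < alpha),
        alpha=alpha,
    )


def compare_wear_time(
    wear_by_group: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> GroupComparisonResult:
    """Full omnibus + post hoc comparison of per-subject mean wear fractions."""
    return dunn_posthoc(wear_by_group, alpha=alpha)
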