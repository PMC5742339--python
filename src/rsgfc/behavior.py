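"""Behavioral scoring, volumetrics adjustment and brain-behavior associations.

Scoring covers a 10-item trait-anger questionnaire (4-point frequency scale,
sum score), a game-round emotion-cluster rating (0-6 intensity, averaged over
all rounds and periods), and a 17-item military stress-symptom checklist
scored with four hyperarousal-related items removed to avoid circularity with
anger measures.  Regional gray-matter volumes are adjusted by dividing by
intracranial volume.  Brain-behavior associations use Spearman rank
correlation (average ranks for ties, two-tailed p via the t approximation)
with FDR adjustment applied within declared association families; group
contrasts use Welch's two-sample t.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gfc import fdr_adjust

__all__ = [
    "AssociationResult",
    "score_trait_anger",
    "cronbach_alpha",
    "score_pcl",
    "score_anger_cluster",
    "adjusted_volume",
    "spearman_assoc",
    "associate_families",
    "group_compare",
]

PCL_REMOVED_DEFAULT = frozenset({5, 14, 16, 17})  # 1-based item numbers


@dataclass
class AssociationResult:
    pair: str
    n: int
    rho: float
    p: float
    family: str
    q_adj: float | None = None


def _check_range(items: np.ndarray, lo: int, hi: int, what: str) -> None:
    if np.isnan(items).any():
        raise ValueError(f"{what}: missing item response")
    if ((items < lo) | (items > hi)).any():
        raise ValueError(f"{what}: responses must lie in {lo}..{hi}")


def score_trait_anger(items: Sequence[float]) -> int:
    """Sum score of the 10 trait-anger items (each 1-4; total 10-40)."""
    x = np.asarray(items, dtype=float)
    if x.shape != (10,):
        raise ValueError("trait-anger requires exactly 10 items")
    _check_range(x, 1, 4, "trait-anger")
    return int(x.sum())


def cronbach_alpha(item_matrix: np.ndarray) -> float:
    """Internal-consistency alpha: k/(k-1) * (1 - sum(var_item)/var(total))."""
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2 or x.shape[0] < 3:
        raise ValueError("need >= 3 subjects and >= 2 items")
    item_var = x.var(axis=0, ddof=1)
    if (item_var == 0).any():
        raise ValueError(f"zero-variance items: {np.flatnonzero(item_var == 0).tolist()}")
    total_var = x.sum(axis=1).var(ddof=1)
    k = x.shape[1]
    return float(k / (k - 1) * (1 - item_var.sum() / total_var))


def score_pcl(
    items: Sequence[float], removed_items: frozenset[int] | set[int] = PCL_REMOVED_DEFAULT
) -> int:
    """Stress-symptom checklist sum over the retained items.

    17 items on a 1-5 scale; the default removal set {5, 14, 16, 17} (1-based)
    drops the anger-concomitant hyperarousal items, giving a 13-item score in
    13..65.
    """
    x = np.asarray(items, dtype=float)
    if x.shape != (17,):
        raise ValueError("PCL requires exactly 17 items")
    _check_range(x, 1, 5, "PCL")
    if any(i < 1 or i > 17 for i in removed_items):
        raise ValueError("removed item numbers must be 1-based in 1..17")
    keep = [k for k in range(17) if (k + 1) not in removed_items]
    return int(x[keep].sum())


def score_anger_cluster(ratings: np.ndarray) -> float:
    """Mean anger-cluster emotion rating over all rounds and periods.

    ``ratings`` may be any shape (round x period x emotion, or flattened);
    entries are 0-6, NaN marks a missing cell and is excluded from both the
    numerator and the denominator.
    """
    x = np.asarray(ratings, dtype=float).ravel()
    valid = x[~np.isnan(x)]
    if valid.size == 0:
        raise ValueError("no non-missing anger-cluster ratings")
    if ((valid < 0) | (valid > 6)).any():
        raise ValueError("anger-cluster ratings must lie in 0..6")
    return float(valid.mean())


def adjusted_volume(region_mm3: float, icv_mm3: float) -> float:
    """Regional volume normalized by intracranial volume (both mm^3, > 0)."""
    if region_mm3 <= 0 or icv_mm3 <= 0:
        raise ValueError("volumes must be positive")
    return region_mm3 / icv_mm3


def spearman_assoc(
    x: Sequence[float],
    y: Sequence[float],
    pair: str = "",
    family: str = "",
) -> AssociationResult:
    """Spearman rank correlation with pairwise-complete deletion.

    Ties get average ranks; the two-tailed p comes from the t approximation
    ``t = rho * sqrt((n-2)/(1-rho^2))`` with n-2 degrees of freedom.  Requires
    n >= 4 complete pairs.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("inputs must be paired")
    ok = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[ok], ya[ok]
    n = xa.size
    if n < 4:
        raise ValueError(f"need >= 4 complete pairs, got {n}")
    rho, p = stats.spearmanr(xa, ya)
    return AssociationResult(pair=pair, n=n, rho=float(rho), p=float(p), family=family)


def associate_families(
    results: Sequence[AssociationResult], q: float = 0.05, method: str = "by"
) -> pd.DataFrame:
    """FDR-adjust association p-values within each declared family.

    Returns a table (pair, family, n, rho, p, q_adj, significant); the raw p
    is kept alongside the adjusted value so both can be reported.
    """
    df = pd.DataFrame(
        [
            {"pair": r.pair, "family": r.family, "n": r.n, "rho": r.rho, "p": r.p}
            for r in results
        ]
    )
    df["q_adj"] = np.nan
    df["significant"] = False
    for _, idx in df.groupby("family").groups.items():
        q_adj, reject = fdr_adjust(df.loc[idx, "p"].to_numpy(), q, method)
        df.loc[idx, "q_adj"] = q_adj
        df.loc[idx, "significant"] = reject
    return df


def group_compare(
    values: Sequence[float], group_labels: Sequence[str]
) -> tuple[float, float, float]:
    """Welch two-sample t-test between two labeled groups: (t, df, p)."""
    v = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"need exactly 2 groups, got {uniq.tolist()}")
    a, b = v[labels == uniq[0]], v[labels == uniq[1]]
    if a.size < 2 or b.size < 2 or (a.std(ddof=1) == 0 and b.std(ddof=1) == 0):
        raise ValueError("each group needs >= 2 observations with variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
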