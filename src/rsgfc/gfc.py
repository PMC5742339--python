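"""Global functional connectivity (gFC) change analysis.

For every parcel the global FC is the sum of its Fisher-Z correlations with
all other parcels: gFC (all values), gFC+ (strictly positive values only) and
gFC- (strictly negative values only), so gFC = gFC+ + gFC- holds exactly.
Session change is Delta-gFC = rest2 - rest1 per subject and parcel.  A
one-sample t-test across subjects on each parcel's three change values,
followed by FDR control (Benjamini-Yekutieli step-up by default,
Benjamini-Hochberg as an option), screens for parcels whose global
connectivity changed between sessions.

The fixed-positive-set validation guards the gFC+ result against variable
edge support: it freezes the set of parcels significantly positively
connected to the seed parcel in BOTH sessions and re-tests the change of the
seed's summed connectivity restricted to that set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectivity import ConnectivityMatrix

__all__ = [
    "TTestResult",
    "FixedPositiveSet",
    "gfc_values",
    "gfc_table",
    "delta_gfc",
    "one_sample_t",
    "t_from_summary",
    "critical_t",
    "fdr_adjust",
    "gfc_change_screen",
    "fixed_positive_set",
    "restricted_delta_gfc",
]

MEASURES = ("gfc", "gfc_pos", "gfc_neg")


@dataclass(frozen=True)
class TTestResult:
    mean: float
    sd: float
    n: int
    t: float
    df: int
    p: float


@dataclass
class FixedPositiveSet:
    """Parcels significantly positively connected to the seed in both sessions."""

    seed: str
    members: list[str]
    alpha: float
    stats: pd.DataFrame  # parcel, session, mean_z, t, p


# ---------------------------------------------------------------------------
# gFC statistics
# ---------------------------------------------------------------------------


def gfc_values(conn: ConnectivityMatrix) -> pd.DataFrame:
    """Per-parcel (gfc, gfc_pos, gfc_neg): off-diagonal row sums of Fisher-Z.

    Strictly positive entries feed gfc_pos, strictly negative entries
    gfc_neg; exact zeros contribute to neither, so gfc = gfc_pos + gfc_neg
    holds identically.
    """
    z = conn.z.copy()
    np.fill_diagonal(z, 0.0)
    pos = np.where(z > 0, z, 0.0).sum(axis=1)
    neg = np.where(z < 0, z, 0.0).sum(axis=1)
    return pd.DataFrame(
        {"parcel": conn.parcel_ids, "gfc": pos + neg, "gfc_pos": pos, "gfc_neg": neg}
    )


def gfc_table(conns: Iterable[ConnectivityMatrix]) -> pd.DataFrame:
    """Tidy table over subjects and sessions: subject, session, parcel, 3 measures."""
    frames = []
    for conn in conns:
        df = gfc_values(conn)
        df.insert(0, "session", conn.session)
        df.insert(0, "subject", conn.subject)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def delta_gfc(gfc_rest1: pd.DataFrame, gfc_rest2: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-parcel session deltas (rest2 - rest1) of the 3 measures.

    Inputs are gfc tables (or slices of :func:`gfc_table`) for each session;
    subjects and parcels must match exactly.
    """
    k = ["subject", "parcel"]
    a = gfc_rest1.set_index(k).sort_index()
    b = gfc_rest2.set_index(k).sort_index()
    if not a.index.equals(b.index):
        raise ValueError("subject/parcel sets differ between sessions")
    out = pd.DataFrame(index=a.index)
    for m in MEASURES:
        out[f"d{m}"] = b[m] - a[m]
    return out.reset_index()


def split_sessions(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    return (
        table[table["session"] == "rest1"].drop(columns="session"),
        table[table["session"] == "rest2"].drop(columns="session"),
    )


# ---------------------------------------------------------------------------
# Inference primitives
# ---------------------------------------------------------------------------


def one_sample_t(values: Sequence[float] | np.ndarray) -> TTestResult:
    """Two-tailed one-sample t-test of the mean against zero."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate sample: zero standard deviation")
    mean = float(x.mean())
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return TTestResult(mean=mean, sd=sd, n=n, t=float(t), df=n - 1, p=float(p))


def t_from_summary(mean: float, sd: float, n: int) -> TTestResult:
    """One-sample t recomputed from reported summary statistics (mean, SD, n)."""
    if sd <= 0 or n < 2:
        raise ValueError("need sd > 0 and n >= 2")
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return TTestResult(mean=mean, sd=sd, n=n, t=float(t), df=n - 1, p=float(p))


def critical_t(df: int, alpha: float = 0.05) -> float:
    """Two-tailed critical value of the central t distribution."""
    if df < 1 or not 0 < alpha < 1:
        raise ValueError("need df >= 1 and 0 < alpha < 1")
    return float(stats.t.ppf(1 - alpha / 2, df))


def fdr_adjust(
    p_values: Sequence[float] | np.ndarray, q: float = 0.05, method: str = "by"
) -> tuple[np.ndarray, np.ndarray]:
    """FDR step-up control: Benjamini-Yekutieli (default) or Benjamini-Hochberg.

    Returns (adjusted q-values, boolean rejection mask) at level ``q``.  BY
    divides the BH thresholds by ``c(m) = sum_{j<=m} 1/j`` and is valid under
    arbitrary dependence between the tests.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    key = {"by": "fdr_by", "bh": "fdr_bh"}.get(method.lower())
    if key is None:
        raise ValueError(f"unknown FDR method {method!r} (use 'by' or 'bh')")
    reject, q_adj, *_ = multipletests(p, alpha=q, method=key)
    return np.minimum(q_adj, 1.0), reject


# ---------------------------------------------------------------------------
# The screen
# ---------------------------------------------------------------------------


def gfc_change_screen(
    deltas: pd.DataFrame,
    q: float = 0.05,
    method: str = "by",
    family: str = "per-measure",
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """One-sample t per (parcel, measure) on the session deltas, with FDR.

    ``deltas`` is the output of :func:`delta_gfc`.  ``family`` selects how the
    FDR correction groups the tests: ``per-measure`` corrects each measure's
    parcel family separately (three corrections of size P), ``pooled`` corrects
    all 3*P tests together.  Returns the full result table and the detected
    (parcel, measure) pairs.
    """
    if family not in ("per-measure", "pooled"):
        raise ValueError(f"unknown family {family!r}")
    # vectorized across parcels; a degenerate unit (zero SD, e.g. an all-zero
    # gfc_neg column when every edge is positive) gets NaN statistics and is
    # excluded from the FDR family instead of aborting the screen
    wide = deltas.pivot(index="subject", columns="parcel")
    n = wide.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    rows = []
    for measure in MEASURES:
        block = wide[f"d{measure}"]
        mean = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(sd > 0, mean / (sd / np.sqrt(n)), np.nan)
        p = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(t), n - 1), np.nan)
        for k, parcel in enumerate(block.columns):
            rows.append(
                {
                    "parcel": parcel,
                    "measure": measure,
                    "mean": mean.iloc[k],
                    "sd": sd.iloc[k],
                    "n": n,
                    "t": t[k],
                    "df": n - 1,
                    "p": p[k],
                }
            )
    table = pd.DataFrame(rows)
    table["q_adj"] = np.nan
    table["significant"] = False

    def _adjust(idx) -> None:
        ok = idx[table.loc[idx, "p"].notna()]
        if len(ok) == 0:
            return
        q_adj, reject = fdr_adjust(table.loc[ok, "p"].to_numpy(), q, method)
        table.loc[ok, "q_adj"] = q_adj
        table.loc[ok, "significant"] = reject

    if family == "pooled":
        _adjust(table.index)
    else:
        for measure in MEASURES:
            _adjust(table.index[table["measure"] == measure])
    detected = [
        (r.parcel, r.measure) for r in table.itertuples(index=False) if r.significant
    ]
    return table, detected


# ---------------------------------------------------------------------------
# Fixed-positive-set validation
# ---------------------------------------------------------------------------


def _seed_edges(conns: Sequence[ConnectivityMatrix], seed: str) -> pd.DataFrame:
    """Long table of z(seed, parcel) per subject, session and other parcel."""
    rows = []
    for conn in conns:
        s = conn.parcel_ids.index(seed)
        for j, pid in enumerate(conn.parcel_ids):
            if pid == seed:
                continue
            rows.append(
                {
                    "subject": conn.subject,
                    "session": conn.session,
                    "parcel": pid,
                    "z": conn.z[s, j],
                }
            )
    return pd.DataFrame(rows)


def fixed_positive_set(
    seed: str, conns: Sequence[ConnectivityMatrix], alpha: float = 0.05
) -> FixedPositiveSet:
    """Parcels with significant positive FC to the seed in both sessions.

    Per parcel and session, the across-subject z(seed, parcel) values are
    tested against zero (two-tailed, uncorrected alpha); membership requires
    p < alpha AND a positive mean in both sessions.
    """
    edges = _seed_edges(conns, seed)
    rows = []
    for (pid, session), grp in edges.groupby(["parcel", "session"], sort=True):
        res = one_sample_t(grp["z"].to_numpy())
        rows.append(
            {"parcel": pid, "session": session, "mean_z": res.mean, "t": res.t, "p": res.p}
        )
    table = pd.DataFrame(rows)
    ok = table[(table["p"] < alpha) & (table["mean_z"] > 0)]
    counts = ok.groupby("parcel").size()
    members = sorted(counts[counts == 2].index.tolist())
    return FixedPositiveSet(seed=seed, members=members, alpha=alpha, stats=table)


def restricted_delta_gfc(
    seed: str,
    member_set: Sequence[str],
    conns: Sequence[ConnectivityMatrix],
) -> tuple[pd.DataFrame, TTestResult]:
    """Seed-connectivity change restricted to a fixed member set.

    Per subject and session, the seed's z values to every member are summed
    (all entries, regardless of their per-subject sign — the set is fixed);
    the per-subject delta (rest2 - rest1) is then tested against zero.
    Returns the per-subject table (columns rest1, rest2, delta) and the t-test.
    """
    members = list(member_set)
    if not members:
        raise ValueError("member set is empty")
    edges = _seed_edges(conns, seed)
    edges = edges[edges["parcel"].isin(members)]
    sums = edges.groupby(["subject", "session"])["z"].sum().unstack("session")
    if set(sums.columns) != {"rest1", "rest2"}:
        raise ValueError("need both rest1 and rest2 sessions for every subject")
    sums["delta"] = sums["rest2"] - sums["rest1"]
    return sums, one_sample_t(sums["delta"].to_numpy())
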