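"""Pairwise (edge-level) connectivity change tests.

Two scopes: the whole-brain screen over all P(P-1)/2 edges (the first-pass
analysis, which on realistic designs is underpowered and typically null), and
the seed-restricted follow-up over the P-1 edges of one seed parcel, used to
individuate which specific connections drive a global-connectivity change.
Both run the same paired statistic — a one-sample t across subjects on the
per-subject Fisher-Z session difference — with FDR step-up control over the
in-scope family.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import ConnectivityMatrix
from .gfc import fdr_adjust

__all__ = ["edge_change_test", "count_increased_edges"]


def _stack_sessions(
    conns: Sequence[ConnectivityMatrix],
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """(z_rest1, z_rest2) arrays of shape (subjects, P, P) with aligned order."""
    by_key = {(c.subject, c.session): c for c in conns}
    subjects = sorted({c.subject for c in conns})
    parcel_ids = conns[0].parcel_ids
    for c in conns:
        if c.parcel_ids != parcel_ids:
            raise ValueError("parcel order differs between connectivity matrices")
    z1, z2 = [], []
    for s in subjects:
        if (s, "rest1") not in by_key or (s, "rest2") not in by_key:
            raise ValueError(f"subject {s} lacks a session")
        z1.append(by_key[(s, "rest1")].z)
        z2.append(by_key[(s, "rest2")].z)
    return np.stack(z1), np.stack(z2), subjects, parcel_ids


def edge_change_test(
    conns: Sequence[ConnectivityMatrix],
    scope: str = "whole_brain",
    seed: str | None = None,
    q: float = 0.05,
    method: str = "by",
) -> pd.DataFrame:
    """Per-edge session-change test with FDR over the in-scope family.

    Returns a table with one row per edge (i < j by parcel ID): mean_dz, sd,
    t, df, p, q_adj and the significance flag at level ``q``.
    """
    if scope not in ("whole_brain", "seed_restricted"):
        raise ValueError(f"unknown scope {scope!r}")
    if (scope == "seed_restricted") != (seed is not None):
        raise ValueError("seed must be given exactly for seed_restricted scope")
    z1, z2, _, parcel_ids = _stack_sessions(conns)
    n, p_count, _ = z1.shape
    dz = z2 - z1  # subjects x P x P
    if scope == "whole_brain":
        ii, jj = np.triu_indices(p_count, k=1)
    else:
        s = parcel_ids.index(seed)  # type: ignore[arg-type]
        others = np.array([k for k in range(p_count) if k != s])
        ii = np.minimum(s, others)
        jj = np.maximum(s, others)
    d = dz[:, ii, jj]  # subjects x edges
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    if (sd == 0).any():
        k = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(
            f"degenerate edge ({parcel_ids[ii[k]]}, {parcel_ids[jj[k]]}): zero SD"
        )
    t = mean / (sd / np.sqrt(n))
    pvals = 2.0 * stats.t.sf(np.abs(t), n - 1)
    q_adj, reject = fdr_adjust(pvals, q, method)
    return pd.DataFrame(
        {
            "i": [parcel_ids[a] for a in ii],
            "j": [parcel_ids[b] for b in jj],
            "mean_dz": mean,
            "sd": sd,
            "t": t,
            "df": n - 1,
            "p": pvals,
            "q_adj": q_adj,
            "significant": reject,
        }
    )


def count_increased_edges(conns: Sequence[ConnectivityMatrix], seed: str) -> int:
    """Number of seed edges whose group-level connectivity t rose in session 2.

    Per session and seed edge, the across-subject z values are summarized by a
    one-sample t against zero; an edge counts as increased when
    t(rest2) > t(rest1) — the construction behind a per-session t-vs-t scatter
    of all seed connections.
    """
    z1, z2, _, parcel_ids = _stack_sessions(conns)
    n = z1.shape[0]
    s = parcel_ids.index(seed)
    others = np.array([k for k in range(len(parcel_ids)) if k != s])

    def session_t(z: np.ndarray) -> np.ndarray:
        vals = z[:, s, others]
        return vals.mean(axis=0) / (vals.std(axis=0, ddof=1) / np.sqrt(n))

    return int((session_t(z2) > session_t(z1)).sum())
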