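"""Per-subject, per-session functional connectivity matrices.

Functional connectivity between two parcels is the Pearson correlation of
their cleaned signals; the full matrix is then Fisher-Z transformed
(``z = arctanh(r)``), which stabilizes the variance of the correlation
estimate.  The diagonal (self-connection) is invalid after the transform and
is stored as NaN; every downstream sum excludes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import ParcelTimeSeries

__all__ = [
    "ConnectivityMatrix",
    "correlation_matrix",
    "fisher_z",
    "connectivity_from_timeseries",
    "save_matrix",
    "load_matrix",
    "write_manifest",
    "load_manifest",
]

CLAMP = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-Z connectivity matrix for one subject-session."""

    z: np.ndarray
    parcel_ids: list[str]
    subject: str
    session: str
    n_clamped: int = 0

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        p = self.z.shape[0]
        if self.z.shape != (p, p):
            raise ValueError("connectivity matrix must be square")
        if len(self.parcel_ids) != p:
            raise ValueError("parcel_ids length mismatch")
        off = ~np.eye(p, dtype=bool)
        if not np.isfinite(self.z[off]).all():
            raise ValueError("non-finite off-diagonal Fisher-Z values")
        if not np.allclose(self.z[off], self.z.T[off], equal_nan=True):
            raise ValueError("connectivity matrix must be symmetric")

    def edge(self, i: int, j: int) -> float:
        return float(self.z[i, j])


def correlation_matrix(ts: ParcelTimeSeries | np.ndarray) -> np.ndarray:
    """Pearson correlation between every pair of parcel signals.

    Requires at least 3 timepoints and no zero-variance parcel; a degenerate
    parcel is reported by ID (or column index for raw arrays).
    """
    if isinstance(ts, ParcelTimeSeries):
        arr, ids = ts.data, ts.parcel_ids
    else:
        arr = np.asarray(ts, dtype=float)
        ids = [str(i) for i in range(arr.shape[1])]
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 timepoints for a correlation matrix")
    sd = arr.std(axis=0)
    if (sd == 0).any():
        bad = [ids[k] for k in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance parcels: {bad}")
    r = np.corrcoef(arr, rowvar=False)
    r = np.clip((r + r.T) / 2, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def fisher_z(
    r_matrix: np.ndarray,
    parcel_ids: Sequence[str] | None = None,
    subject: str = "",
    session: str = "",
) -> ConnectivityMatrix:
    """Fisher-Z transform of a correlation matrix.

    Off-diagonal values with ``|r| >= 1 - 1e-7`` are clamped to keep z finite
    (z ≈ ±8.1); the number of clamped entries is recorded on the result.  The
    diagonal is set to NaN (self-connection undefined).
    """
    r = np.asarray(r_matrix, dtype=float)
    if np.nanmax(np.abs(r)) > 1 + 1e-12:
        raise ValueError("correlations must satisfy |r| <= 1")
    p = r.shape[0]
    off = ~np.eye(p, dtype=bool)
    clipped = np.clip(r, -CLAMP, CLAMP)
    n_clamped = int(((np.abs(r) > CLAMP) & off).sum() // 2)
    z = np.arctanh(clipped)
    np.fill_diagonal(z, np.nan)
    if parcel_ids is None:
        parcel_ids = [f"p{i:03d}" for i in range(p)]
    return ConnectivityMatrix(
        z=z, parcel_ids=list(parcel_ids), subject=subject, session=session,
        n_clamped=n_clamped,
    )


def connectivity_from_timeseries(ts: ParcelTimeSeries) -> ConnectivityMatrix:
    """Pearson + Fisher-Z in one step, carrying subject/session metadata."""
    return fisher_z(
        correlation_matrix(ts), ts.parcel_ids, subject=ts.subject, session=ts.session
    )


# ---------------------------------------------------------------------------
# TSV round-trip
# ---------------------------------------------------------------------------


def save_matrix(conn: ConnectivityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(conn.z, index=conn.parcel_ids, columns=conn.parcel_ids)
    df.to_csv(path, sep="\t")


def load_matrix(path: str | Path, subject: str = "", session: str = "") -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ConnectivityMatrix(
        z=df.to_numpy(), parcel_ids=[str(c) for c in df.columns],
        subject=subject, session=session,
    )


def write_manifest(entries: list[tuple[str, str, str]], path: str | Path) -> None:
    """Manifest rows: (subject, session, relative path to matrix TSV)."""
    pd.DataFrame(entries, columns=["subject", "session", "path"]).to_csv(
        path, sep="\t", index=False
    )


def load_manifest(path: str | Path) -> list["ConnectivityMatrix"]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        out.append(load_matrix(path.parent / row.path, subject=row.subject, session=row.session))
    return out
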