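"""Signal-cleaning chain for parcel-level BOLD time series.

Stages, in the fixed order they run: lead-volume trimming, ideal FFT band-pass
filtering (0.01–0.08 Hz by default), parcellation of voxel data under a
gray-matter mask (when the input is a 4D image rather than parcel series),
nuisance regression of motion/WM/CSF (optionally the global mean) confounds,
and head-motion quality control (framewise displacement and a hard exclusion
threshold on absolute displacement).

Each stage stamps a provenance flag on the :class:`ParcelTimeSeries`; running
a stage twice on the same series is an error, which pins the pipeline order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ParcelTimeSeries",
    "QcRecord",
    "PipelineOrderError",
    "trim_volumes",
    "bandpass_filter",
    "bandpass_array",
    "parcellate",
    "regress_nuisance",
    "framewise_displacement",
    "motion_exclusion",
]


class PipelineOrderError(RuntimeError):
    """A preprocessing stage was re-run on already-processed data."""


@dataclass
class ParcelTimeSeries:
    """Cleaned (or in-progress) parcel signals for one subject-session.

    ``data`` is timepoints x parcels.  ``flags`` records which stages have run;
    ``flagged_parcels`` lists parcels whose signal became degenerate (zero
    variance) during cleaning — they are carried along, never silently dropped.
    """

    data: np.ndarray
    parcel_ids: list[str]
    tr_seconds: float
    subject: str = ""
    session: str = ""
    flags: frozenset[str] = frozenset()
    flagged_parcels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be 2-D (timepoints x parcels)")
        if self.data.shape[1] != len(self.parcel_ids):
            raise ValueError("parcel_ids length does not match data columns")
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite values in time-series data")

    @classmethod
    def from_array(
        cls, data: np.ndarray, tr_seconds: float, parcel_ids: Sequence[str] | None = None, **kw
    ) -> "ParcelTimeSeries":
        data = np.asarray(data, dtype=float)
        if parcel_ids is None:
            parcel_ids = [f"p{i:03d}" for i in range(data.shape[1])]
        return cls(data=data, parcel_ids=list(parcel_ids), tr_seconds=tr_seconds, **kw)

    def _stamped(self, stage: str, data: np.ndarray) -> "ParcelTimeSeries":
        if stage in self.flags:
            raise PipelineOrderError(f"stage {stage!r} already applied to this series")
        sd = data.std(axis=0)
        degenerate = [pid for pid, s in zip(self.parcel_ids, sd) if s == 0]
        return replace(
            self,
            data=data,
            flags=self.flags | {stage},
            flagged_parcels=sorted(set(self.flagged_parcels) | set(degenerate)),
        )


@dataclass
class QcRecord:
    """Per subject-session motion QC summary."""

    subject: str
    session: str
    mean_fd: float
    max_translation_mm: float
    max_rotation_deg: float
    excluded: bool


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def trim_volumes(ts: ParcelTimeSeries | np.ndarray, n_drop: int = 6):
    """Drop the first ``n_drop`` volumes (T2* equilibration lead volumes)."""
    arr = ts.data if isinstance(ts, ParcelTimeSeries) else np.asarray(ts, dtype=float)
    if n_drop < 0:
        raise ValueError("n_drop must be >= 0")
    if n_drop >= arr.shape[0]:
        raise ValueError(f"cannot drop {n_drop} of {arr.shape[0]} volumes")
    out = arr[n_drop:]
    if isinstance(ts, ParcelTimeSeries):
        return ts._stamped("trimmed", out)
    return out


def bandpass_array(
    arr: np.ndarray, low_hz: float, high_hz: float, tr_seconds: float
) -> np.ndarray:
    """Ideal (frequency-domain) band-pass per column.

    Demeans, takes the real FFT, zeroes every frequency bin strictly outside
    ``[low_hz, high_hz]`` and inverts.  The DC bin is always removed by the
    demeaning; a bin exactly on a band edge is retained.
    """
    arr = np.asarray(arr, dtype=float)
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not 0 <= low_hz < high_hz:
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz > nyquist + 1e-12:
        raise ValueError(f"high_hz {high_hz} exceeds Nyquist frequency {nyquist:.4g} Hz")
    n = arr.shape[0]
    demeaned = arr - arr.mean(axis=0)
    spectrum = np.fft.rfft(demeaned, axis=0)
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    keep = (freqs >= low_hz - 1e-12) & (freqs <= high_hz + 1e-12)
    spectrum[~keep] = 0.0
    return np.fft.irfft(spectrum, n=n, axis=0)


def bandpass_filter(
    ts: ParcelTimeSeries | np.ndarray,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    tr_seconds: float | None = None,
):
    """Band-pass to low-frequency fluctuations (defaults 0.01–0.08 Hz)."""
    if isinstance(ts, ParcelTimeSeries):
        out = bandpass_array(ts.data, low_hz, high_hz, ts.tr_seconds)
        return ts._stamped("filtered", out)
    if tr_seconds is None:
        raise ValueError("tr_seconds required for array input")
    return bandpass_array(np.asarray(ts), low_hz, high_hz, tr_seconds)


def _as_array(img):
    if hasattr(img, "get_fdata"):
        return np.asarray(img.get_fdata())
    return np.asarray(img, dtype=float)


def parcellate(
    voxel_data,
    atlas_labels,
    gm_mask,
    min_common_voxels: int = 5,
    tr_seconds: float = 3.0,
) -> tuple[ParcelTimeSeries, list[str]]:
    """Average voxel signals within each atlas parcel, gray matter only.

    ``voxel_data`` is a 4-D array/NIfTI image (x, y, z, time), ``atlas_labels``
    a 3-D integer label image, ``gm_mask`` a 3-D binary mask on the same grid.
    Parcels sharing fewer than ``min_common_voxels`` voxels with the mask are
    excluded; the exclusion list (parcel IDs) is returned alongside.
    """
    data = _as_array(voxel_data)
    labels = np.asarray(_as_array(atlas_labels), dtype=int)
    mask = _as_array(gm_mask) > 0
    if data.ndim != 4:
        raise ValueError("voxel_data must be 4-D (x, y, z, time)")
    if labels.shape != data.shape[:3] or mask.shape != data.shape[:3]:
        raise ValueError(
            f"image grids disagree: data {data.shape[:3]}, "
            f"labels {labels.shape}, mask {mask.shape}"
        )
    parcel_values = np.unique(labels)
    parcel_values = parcel_values[parcel_values > 0]
    width = max(3, len(str(parcel_values.max())) if parcel_values.size else 3)
    kept_ids, kept_series, excluded = [], [], []
    for label in parcel_values:
        pid = f"p{label:0{width}d}"
        voxels = (labels == label) & mask
        if voxels.sum() < min_common_voxels:
            excluded.append(pid)
            continue
        kept_ids.append(pid)
        kept_series.append(data[voxels].mean(axis=0))
    series = np.column_stack(kept_series) if kept_series else np.empty((data.shape[3], 0))
    return (
        ParcelTimeSeries(data=series, parcel_ids=kept_ids, tr_seconds=tr_seconds),
        excluded,
    )


def regress_nuisance(
    ts: ParcelTimeSeries | np.ndarray,
    confounds: np.ndarray,
    confound_names: Sequence[str] | None = None,
    global_signal: bool = False,
):
    """OLS residual of every parcel signal on [intercept | confounds].

    ``confounds`` is timepoints x k (motion 6 + wm + csf, optionally a global
    channel already appended by the caller).  Rank deficiency after adding the
    intercept is an error naming the collinear columns.  ``global_signal`` only
    stamps the provenance variant flag.
    """
    arr = ts.data if isinstance(ts, ParcelTimeSeries) else np.asarray(ts, dtype=float)
    confounds = np.asarray(confounds, dtype=float)
    if confounds.ndim == 1:
        confounds = confounds[:, None]
    if confounds.shape[0] != arr.shape[0]:
        raise ValueError("confound rows do not match time-series rows")
    if confound_names is None:
        confound_names = [f"c{k}" for k in range(confounds.shape[1])]
    design = np.column_stack([np.ones(arr.shape[0]), confounds])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offenders: columns whose removal restores full rank
        bad = []
        for k in range(confounds.shape[1]):
            reduced = np.delete(design, k + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                bad.append(confound_names[k])
        raise ValueError(f"confound matrix is rank deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, arr, rcond=None)
    resid = arr - design @ beta
    if isinstance(ts, ParcelTimeSeries):
        out = ts._stamped("nuisance_regressed", resid)
        if global_signal:
            out = replace(out, flags=out.flags | {"global_signal_variant"})
        return out
    return resid


# ---------------------------------------------------------------------------
# Motion QC
# ---------------------------------------------------------------------------


def framewise_displacement(
    motion: np.ndarray, sphere_radius_mm: float = 50.0
) -> tuple[np.ndarray, float]:
    """Power-style framewise displacement.

    ``motion`` is timepoints x 6 (tx, ty, tz in mm; rx, ry, rz in degrees).
    FD[0] = 0; FD[t] is the sum of absolute translation steps plus the arc
    length of the rotation steps on a ``sphere_radius_mm`` sphere.  Returns the
    series and the mean over t >= 1.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion table must be timepoints x 6")
    if motion.shape[0] < 2:
        raise ValueError("need at least two timepoints for FD")
    d = np.diff(motion, axis=0)
    trans = np.abs(d[:, :3]).sum(axis=1)
    rot = np.abs(np.deg2rad(d[:, 3:])).sum(axis=1) * sphere_radius_mm
    fd = np.concatenate([[0.0], trans + rot])
    return fd, float(fd[1:].mean())


def motion_exclusion(
    motion: np.ndarray,
    trans_mm: float = 2.0,
    rot_deg: float = 2.0,
    subject: str = "",
    session: str = "",
    sphere_radius_mm: float = 50.0,
) -> QcRecord:
    """QC record with the hard displacement exclusion.

    Displacement is measured as deviation from the session's first volume;
    exclusion requires strictly exceeding the threshold (>2 mm or >2 degrees
    by default).
    """
    motion = np.asarray(motion, dtype=float)
    dev = motion - motion[0]
    max_trans = float(np.abs(dev[:, :3]).max())
    max_rot = float(np.abs(dev[:, 3:]).max())
    _, mean_fd = framewise_displacement(motion, sphere_radius_mm)
    return QcRecord(
        subject=subject,
        session=session,
        mean_fd=mean_fd,
        max_translation_mm=max_trans,
        max_rotation_deg=max_rot,
        excluded=max_trans > trans_mm or max_rot > rot_deg,
    )
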