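"""Synthetic two-session resting-state datasets with planted connectivity changes.

Emulates the study design the pipeline targets: N subjects scanned twice
(``rest1`` before and ``rest2`` after an intervention), parcel-level BOLD-like
time series with a known cross-correlation structure, and a connectivity
increase planted on the edges of one seed parcel in the second session only.
Because the ground-truth correlation matrices and the planted-edge list are
recorded, every downstream stage (preprocessing, connectivity, the global-FC
screen, the seed-edge follow-up) can be validated against known truth.

The temporal model is a stationary Gaussian AR(1) process whose innovation
covariance is chosen so that the stationary cross-correlation of the parcels
equals the target correlation matrix exactly.  Nuisance structure (head-motion
random walks, white-matter and CSF signals, slow scanner drift) is added as
linear contamination so the preprocessing stage has real work to do.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "SyntheticSpec",
    "SessionData",
    "SyntheticDataset",
    "build_truth_covariances",
    "nearest_psd_correlation",
    "apply_z_shift",
    "planted_edges",
    "simulate_session",
    "generate_dataset",
    "write_dataset",
    "spec_from_file",
    "spec_to_file",
]

SESSIONS = ("rest1", "rest2")

MOTION_COLUMNS = ("tx", "ty", "tz", "rx", "ry", "rz")


class PsdRepairError(ValueError):
    """Raised when the PSD repair moves a planted edge by more than tolerance."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of the synthetic study.

    Defaults reproduce the target design: 44 subjects, 463 parcels, two 6-min
    sessions at TR = 3 s (120 volumes of which the first 6 are lead volumes,
    leaving 114), a block-community baseline network, and a diffuse positive
    connectivity increase planted on one seed parcel in session 2.

    Parameters
    ----------
    delta_z : mean planted shift on the Fisher-Z scale, applied edge-wise in
        session 2 (``r -> tanh(arctanh(r) + delta_z)``).
    subject_sd_z : between-subject SD of the planted shift; one draw per
        subject, shared by all of that subject's planted edges.
    effect_targets : for ``focal`` mode an explicit tuple of target parcel
        indices; for ``diffuse`` mode a fraction in (0, 1] of parcels drawn
        (excluding the seed) as targets.
    nuisance_amplitude : SD of the added nuisance component relative to the
        unit-SD neural signal.
    """

    n_subjects: int = 44
    n_parcels: int = 463
    n_timepoints: int = 114
    n_lead_volumes: int = 6
    tr_seconds: float = 3.0
    base_correlation_model: str = "block_community"
    community_count: int = 8
    within_community_r: float = 0.4
    between_community_r: float = 0.05
    seed_node: int = 0
    effect_mode: str = "diffuse"
    effect_targets: float | tuple[int, ...] = 0.3
    delta_z: float = 0.04
    subject_sd_z: float = 0.05
    ar_coefficient: float = 0.3
    nuisance_amplitude: float = 0.5
    motion_step_sd: float = 0.02
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_parcels < 2:
            raise ValueError("n_parcels must be >= 2")
        if self.n_timepoints <= 0:
            raise ValueError("n_timepoints must be positive")
        if self.n_lead_volumes < 0:
            raise ValueError("n_lead_volumes must be >= 0")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.base_correlation_model not in ("block_community", "random_sparse"):
            raise ValueError(f"unknown base model {self.base_correlation_model!r}")
        if self.effect_mode not in ("focal", "diffuse"):
            raise ValueError(f"unknown effect mode {self.effect_mode!r}")
        for name in ("within_community_r", "between_community_r", "ar_coefficient"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ValueError(f"{name} must lie strictly inside (-1, 1)")
        if not 0 <= self.seed_node < self.n_parcels:
            raise ValueError("seed_node out of range")
        if self.delta_z < 0:
            raise ValueError("delta_z must be >= 0")
        if self.subject_sd_z < 0:
            raise ValueError("subject_sd_z must be >= 0")
        if self.nuisance_amplitude < 0:
            raise ValueError("nuisance_amplitude must be >= 0")
        if self.effect_mode == "diffuse":
            if not isinstance(self.effect_targets, (int, float)) or not (
                0 < float(self.effect_targets) <= 1
            ):
                raise ValueError("diffuse effect_targets must be a fraction in (0, 1]")
        else:
            targets = tuple(int(t) for t in self.effect_targets)  # type: ignore[arg-type]
            if len(targets) == 0:
                raise ValueError("focal effect_targets must be non-empty")
            if any(t < 0 or t >= self.n_parcels for t in targets):
                raise ValueError("effect target out of range")
            if self.seed_node in targets:
                raise ValueError("seed_node may not be its own effect target")
            object.__setattr__(self, "effect_targets", targets)

    @property
    def parcel_ids(self) -> list[str]:
        width = max(3, len(str(self.n_parcels)))
        return [f"p{i:0{width}d}" for i in range(self.n_parcels)]

    @property
    def subject_ids(self) -> list[str]:
        width = max(2, len(str(self.n_subjects)))
        return [f"sub-{i + 1:0{width}d}" for i in range(self.n_subjects)]


@dataclass
class SessionData:
    """One subject-session worth of raw generator output (untrimmed)."""

    timeseries: np.ndarray  # (n_lead + n_timepoints) x n_parcels
    motion: np.ndarray  # same rows x 6 (tx,ty,tz in mm; rx,ry,rz in degrees)
    wm: np.ndarray  # white-matter nuisance series
    csf: np.ndarray  # CSF nuisance series


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    sessions: dict[tuple[str, str], SessionData]
    truth_rest1: np.ndarray
    truth_rest2: np.ndarray
    planted: list[tuple[int, int]]
    edge_delta_z: dict[tuple[int, int], float]
    subject_shifts: dict[str, float]

    def session(self, subject: str, session: str) -> SessionData:
        return self.sessions[(subject, session)]


# ---------------------------------------------------------------------------
# Ground-truth correlation structure
# ---------------------------------------------------------------------------


def planted_edges(spec: SyntheticSpec) -> list[tuple[int, int]]:
    """Edges (seed, target) carrying the planted session-2 shift.

    Focal mode uses the explicit target list; diffuse mode draws
    ``round(fraction * n_parcels)`` distinct targets (never the seed itself)
    deterministically from the spec's RNG seed.
    """
    if spec.effect_mode == "focal":
        targets = list(spec.effect_targets)  # type: ignore[arg-type]
    else:
        n_targets = int(round(float(spec.effect_targets) * spec.n_parcels))
        n_targets = min(n_targets, spec.n_parcels - 1)
        candidates = [i for i in range(spec.n_parcels) if i != spec.seed_node]
        rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 7]))
        targets = sorted(rng.choice(candidates, size=n_targets, replace=False).tolist())
    return [(min(spec.seed_node, t), max(spec.seed_node, t)) for t in targets]


def _base_correlation(spec: SyntheticSpec) -> np.ndarray:
    p = spec.n_parcels
    if spec.base_correlation_model == "block_community":
        labels = np.arange(p) % spec.community_count
        same = labels[:, None] == labels[None, :]
        corr = np.where(same, spec.within_community_r, spec.between_community_r)
        np.fill_diagonal(corr, 1.0)
        return corr
    # random_sparse: a sparse symmetric draw pushed to the nearest PSD correlation
    rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 11]))
    corr = np.eye(p)
    mask = np.triu(rng.random((p, p)) < 0.1, k=1)
    vals = rng.uniform(-abs(spec.within_community_r), abs(spec.within_community_r), (p, p))
    corr = corr + mask * vals + (mask * vals).T
    return nearest_psd_correlation(corr)


def nearest_psd_correlation(corr: np.ndarray) -> np.ndarray:
    """Eigenvalue-clipped PSD repair with the diagonal rescaled to 1.

    Negative eigenvalues are clipped at zero and the resulting matrix is
    renormalized ``D^{-1/2} C D^{-1/2}``; a matrix that is already PSD is
    perturbed only at floating-point level.
    """
    corr = np.asarray(corr, dtype=float)
    w, v = np.linalg.eigh((corr + corr.T) / 2)
    if w.min() >= 0:
        return (corr + corr.T) / 2
    w = np.clip(w, 0.0, None)
    repaired = (v * w) @ v.T
    d = np.sqrt(np.diag(repaired))
    d[d == 0] = 1.0
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return (repaired + repaired.T) / 2


def apply_z_shift(
    corr: np.ndarray,
    edges: Iterable[tuple[int, int]],
    shifts: float | Mapping[tuple[int, int], float],
    max_edge_perturbation: float = 0.01,
) -> np.ndarray:
    """Shift edges on the Fisher-Z scale, then repair to a PSD correlation.

    Each listed edge's correlation r is replaced by
    ``tanh(arctanh(r) + shift)``.  If the PSD repair moves any planted edge by
    more than ``max_edge_perturbation``, a :class:`PsdRepairError` names the
    offending edge.
    """
    shifted = np.array(corr, dtype=float, copy=True)
    edges = list(edges)
    for (i, j) in edges:
        s = shifts if isinstance(shifts, (int, float)) else shifts[(i, j)]
        r_new = float(np.tanh(np.arctanh(shifted[i, j]) + s))
        shifted[i, j] = shifted[j, i] = r_new
    repaired = nearest_psd_correlation(shifted)
    for (i, j) in edges:
        if abs(repaired[i, j] - shifted[i, j]) > max_edge_perturbation:
            raise PsdRepairError(
                f"PSD repair moved planted edge ({i}, {j}) by "
                f"{abs(repaired[i, j] - shifted[i, j]):.4f} (> {max_edge_perturbation})"
            )
    return repaired


def build_truth_covariances(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth correlation matrices for (rest1, rest2).

    rest2 equals rest1 with each planted edge shifted by ``delta_z`` on the
    Fisher-Z scale; both matrices are PSD-repaired correlation matrices.
    """
    base = nearest_psd_correlation(_base_correlation(spec))
    if spec.delta_z == 0:
        return base, base.copy()
    session2 = apply_z_shift(base, planted_edges(spec), spec.delta_z)
    return base, session2


# ---------------------------------------------------------------------------
# Time-series simulation
# ---------------------------------------------------------------------------


def _psd_factor(corr: np.ndarray) -> np.ndarray:
    """A factor L with L L' = corr, valid also for singular PSD matrices."""
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(corr)
        w = np.clip(w, 0.0, None)
        return v * np.sqrt(w)


def _ar1_series(factor: np.ndarray, n_rows: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) rows with cross-sectional covariance factor @ factor.T."""
    innov = rng.standard_normal((n_rows, factor.shape[0])) @ factor.T
    if phi == 0:
        return innov
    out = np.empty_like(innov)
    out[0] = innov[0]
    scale = np.sqrt(1.0 - phi * phi)
    for t in range(1, n_rows):
        out[t] = phi * out[t - 1] + scale * innov[t]
    return out


def _drift(n_rows: int, tr: float, rng: np.random.Generator) -> np.ndarray:
    """Slow scanner drift: linear trend + random-phase cosines below 0.008 Hz."""
    t = np.arange(n_rows) * tr
    series = rng.uniform(-1, 1) * (t / max(t[-1], 1.0))
    for f in (0.002, 0.004, 0.006):
        series = series + rng.uniform(0.3, 1.0) * np.cos(
            2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)
        )
    sd = series.std()
    return series / sd if sd > 0 else series


def simulate_session(
    truth_corr: np.ndarray,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    subject_shift: float | Mapping[tuple[int, int], float] | None = None,
    factor: np.ndarray | None = None,
) -> SessionData:
    """Simulate one subject-session.

    The neural signal is a stationary AR(1) Gaussian process whose
    cross-correlation equals ``truth_corr`` (with ``subject_shift`` applied on
    the Fisher-Z scale to the spec's planted edges first, when given).  Motion
    parameters are smooth random walks; WM/CSF are unit-variance AR(1) series;
    nuisance contamination is a linear combination of all nuisance channels plus
    slow drift, scaled by ``nuisance_amplitude``.
    """
    n_rows = spec.n_lead_volumes + spec.n_timepoints
    if subject_shift is not None:
        # per-subject repair is best-effort: the 0.01 gate applies only when
        # constructing the ground-truth matrices
        truth_corr = apply_z_shift(
            truth_corr, planted_edges(spec), subject_shift, max_edge_perturbation=np.inf
        )
        factor = None
    if factor is None:
        factor = _psd_factor(truth_corr)
    neural = _ar1_series(factor, n_rows, spec.ar_coefficient, rng)

    motion = np.cumsum(rng.normal(0.0, spec.motion_step_sd, (n_rows, 6)), axis=0)
    wm = _ar1_series(np.ones((1, 1)), n_rows, 0.8, rng)[:, 0]
    csf = _ar1_series(np.ones((1, 1)), n_rows, 0.8, rng)[:, 0]

    ts = neural
    if spec.nuisance_amplitude > 0:
        drift = _drift(n_rows, spec.tr_seconds, rng)
        channels = np.column_stack([motion, wm, csf, drift])
        sd = channels.std(axis=0)
        sd[sd == 0] = 1.0
        channels = (channels - channels.mean(axis=0)) / sd
        loadings = rng.standard_normal((channels.shape[1], spec.n_parcels))
        loadings /= np.sqrt(channels.shape[1])
        ts = neural + spec.nuisance_amplitude * channels @ loadings
    return SessionData(timeseries=ts, motion=motion, wm=wm, csf=csf)


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Simulate the full study: every subject, both sessions, plus ground truth.

    Each subject draws one planted-shift value ``N(delta_z, subject_sd_z)``
    applied to all planted edges in session 2 only.  Identical specs yield
    bit-identical datasets.
    """
    truth1, truth2 = build_truth_covariances(spec)
    edges = planted_edges(spec)
    factor1 = _psd_factor(truth1)
    root = np.random.SeedSequence([spec.rng_seed, 1])
    shift_rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 2]))
    children = root.spawn(spec.n_subjects * 2)

    sessions: dict[tuple[str, str], SessionData] = {}
    subject_shifts: dict[str, float] = {}
    has_effect = spec.delta_z > 0 or spec.subject_sd_z > 0
    for s_idx, subject in enumerate(spec.subject_ids):
        shift = float(shift_rng.normal(spec.delta_z, spec.subject_sd_z)) if has_effect else 0.0
        subject_shifts[subject] = shift
        rng1 = np.random.default_rng(children[2 * s_idx])
        rng2 = np.random.default_rng(children[2 * s_idx + 1])
        sessions[(subject, "rest1")] = simulate_session(truth1, spec, rng1, factor=factor1)
        sessions[(subject, "rest2")] = simulate_session(
            truth1, spec, rng2, subject_shift=shift if has_effect else None,
            factor=None if has_effect else factor1,
        )
    return SyntheticDataset(
        spec=spec,
        sessions=sessions,
        truth_rest1=truth1,
        truth_rest2=truth2,
        planted=edges,
        edge_delta_z={e: spec.delta_z for e in edges},
        subject_shifts=subject_shifts,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> Path:
    """Write one TSV per subject-session (time series, motion, nuisance) plus a
    ground-truth JSON sidecar and the spec itself."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = dataset.spec
    for (subject, session), data in dataset.sessions.items():
        stem = f"{subject}_{session}"
        pd.DataFrame(data.timeseries, columns=spec.parcel_ids).to_csv(
            outdir / f"{stem}_timeseries.tsv", sep="\t", index=False
        )
        pd.DataFrame(data.motion, columns=list(MOTION_COLUMNS)).to_csv(
            outdir / f"{stem}_motion.tsv", sep="\t", index=False
        )
        pd.DataFrame({"wm": data.wm, "csf": data.csf}).to_csv(
            outdir / f"{stem}_nuisance.tsv", sep="\t", index=False
        )
    truth = {
        "rng_seed": spec.rng_seed,
        "planted_edges": [
            {"i": i, "j": j, "delta_z": dataset.edge_delta_z[(i, j)]}
            for (i, j) in dataset.planted
        ],
        "subject_shifts": dataset.subject_shifts,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    spec_to_file(spec, outdir / "spec.json")
    return outdir


def spec_to_file(spec: SyntheticSpec, path: str | Path) -> None:
    path = Path(path)
    payload = dataclasses.asdict(spec)
    if isinstance(payload["effect_targets"], tuple):
        payload["effect_targets"] = list(payload["effect_targets"])
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2))


def spec_from_file(path: str | Path) -> SyntheticSpec:
    path = Path(path)
    text = path.read_text()
    payload = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    known = {f.name for f in dataclasses.fields(SyntheticSpec)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown spec keys: {sorted(unknown)}")
    if isinstance(payload.get("effect_targets"), list):
        payload["effect_targets"] = tuple(payload["effect_targets"])
    return SyntheticSpec(**payload)
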