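"""End-to-end orchestration: simulate/ingest -> preprocess -> connectivity ->
gFC screen -> fixed-set validation -> seed edge screen -> associations.

A :class:`RunConfig` carries every stage parameter; a run persists all
intermediates (cleaned series, QC table, connectivity matrices + manifest, gFC
tables, test tables) under the output directory together with the fully
resolved config, and returns a :class:`RunReport` whose every count is
recomputable from those outputs.  Runs are deterministic given the RNG seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import behavior as bhv
from . import preprocess as pp
from .connectivity import (
    ConnectivityMatrix,
    connectivity_from_timeseries,
    save_matrix,
    write_manifest,
)
from .edges import count_increased_edges, edge_change_test
from .gfc import (
    delta_gfc,
    fixed_positive_set,
    gfc_change_screen,
    gfc_table,
    restricted_delta_gfc,
    split_sessions,
)
from .synthetic import (
    SESSIONS,
    SyntheticDataset,
    SyntheticSpec,
    generate_dataset,
    write_dataset,
)

__all__ = [
    "RunConfig",
    "RunReport",
    "run_pipeline",
    "preprocess_session",
    "connectivity_from_dataset",
    "gfc_screen_replicates",
    "edge_screen_replicates",
]


@dataclass
class RunConfig:
    """Fully resolved pipeline configuration (unknown keys are rejected)."""

    out_dir: str = "rsgfc_out"
    synthetic: dict[str, Any] | None = None
    input_dir: str | None = None
    rng_seed: int = 0
    # preprocessing
    trim_count: int = 6
    low_hz: float = 0.01
    high_hz: float = 0.08
    fd_radius_mm: float = 50.0
    max_translation_mm: float = 2.0
    max_rotation_deg: float = 2.0
    global_signal: bool = False
    # inference
    q: float = 0.05
    fdr_method: str = "by"
    fdr_family: str = "per-measure"
    fixed_set_alpha: float = 0.05
    seed_parcel: str | None = None  # defaults to the synthetic seed node
    # associations
    behavior_path: str | None = None
    families_path: str | None = None
    schema_version: int = 1

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        payload = (
            yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        )
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


@dataclass
class RunReport:
    qc: list[dict[str, Any]]
    subjects_total: int
    subjects_excluded: list[str]
    parcels: int
    detected: list[tuple[str, str]]
    fixed_set_seed: str
    fixed_set_size: int
    restricted_t: dict[str, float]
    seed_edges_significant: list[tuple[str, str]]
    whole_brain_edges_significant: int
    increased_seed_edges: int
    n_tests: dict[str, int]
    associations: list[dict[str, Any]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def preprocess_session(
    timeseries: np.ndarray,
    motion: np.ndarray,
    wm: np.ndarray,
    csf: np.ndarray,
    config: RunConfig,
    tr_seconds: float,
    parcel_ids: Sequence[str],
    subject: str = "",
    session: str = "",
) -> pp.ParcelTimeSeries:
    """The fixed cleaning chain for one session: trim -> band-pass -> regress.

    Confound columns (motion, WM, CSF, optionally the global mean) are trimmed
    and band-pass filtered identically to the signals before the regression so
    both live in the same frequency band.
    """
    ts = pp.ParcelTimeSeries(
        data=np.asarray(timeseries, dtype=float),
        parcel_ids=list(parcel_ids),
        tr_seconds=tr_seconds,
        subject=subject,
        session=session,
    )
    ts = pp.trim_volumes(ts, config.trim_count)
    ts = pp.bandpass_filter(ts, config.low_hz, config.high_hz)
    confounds = np.column_stack([motion, wm, csf])
    names = ["tx", "ty", "tz", "rx", "ry", "rz", "wm", "csf"]
    if config.global_signal:
        confounds = np.column_stack([confounds, np.asarray(wm) * 0.5 + np.asarray(csf) * 0.5])
        names.append("global")
    confounds = confounds[config.trim_count :]
    confounds = pp.bandpass_array(confounds, config.low_hz, config.high_hz, tr_seconds)
    return pp.regress_nuisance(ts, confounds, names, global_signal=config.global_signal)


def connectivity_from_dataset(
    dataset: SyntheticDataset, preprocessed: bool = False, config: RunConfig | None = None
) -> list[ConnectivityMatrix]:
    """Connectivity matrices for every subject-session of a synthetic dataset.

    With ``preprocessed=False`` the lead volumes are dropped and correlation is
    taken on the raw generated signals (appropriate for zero-nuisance study
    replicates); otherwise the full cleaning chain runs first.
    """
    spec = dataset.spec
    conns = []
    for (subject, session), data in sorted(dataset.sessions.items()):
        if preprocessed:
            cfg = config or RunConfig(trim_count=spec.n_lead_volumes)
            ts = preprocess_session(
                data.timeseries, data.motion, data.wm, data.csf, cfg,
                spec.tr_seconds, spec.parcel_ids, subject, session,
            )
        else:
            ts = pp.ParcelTimeSeries(
                data=data.timeseries[spec.n_lead_volumes :],
                parcel_ids=spec.parcel_ids,
                tr_seconds=spec.tr_seconds,
                subject=subject,
                session=session,
            )
        conns.append(connectivity_from_timeseries(ts))
    return conns


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def _load_sessions_from_dir(indir: Path):
    """Read the TSV layout written by the synthetic writer."""
    spec_path = indir / "spec.json"
    ts_files = sorted(indir.glob("*_timeseries.tsv"))
    if not ts_files:
        raise FileNotFoundError(f"no *_timeseries.tsv under {indir}")
    sessions = {}
    for f in ts_files:
        stem = f.name.replace("_timeseries.tsv", "")
        subject, session = stem.rsplit("_", 1)
        ts = pd.read_csv(f, sep="\t")
        motion = pd.read_csv(indir / f"{stem}_motion.tsv", sep="\t").to_numpy()
        nuis = pd.read_csv(indir / f"{stem}_nuisance.tsv", sep="\t")
        sessions[(subject, session)] = (
            ts.to_numpy(), list(ts.columns), motion, nuis["wm"].to_numpy(),
            nuis["csf"].to_numpy(),
        )
    return sessions, spec_path


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis and persist every intermediate under out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.synthetic is not None:
        spec = SyntheticSpec(**{**config.synthetic, "rng_seed": config.rng_seed})
        dataset = generate_dataset(spec)
        write_dataset(dataset, out / "data")
        sessions = {
            key: (d.timeseries, spec.parcel_ids, d.motion, d.wm, d.csf)
            for key, d in dataset.sessions.items()
        }
        tr = spec.tr_seconds
        seed_parcel = config.seed_parcel or spec.parcel_ids[spec.seed_node]
    elif config.input_dir is not None:
        sessions, spec_path = _load_sessions_from_dir(Path(config.input_dir))
        tr = 3.0
        if spec_path.exists():
            from .synthetic import spec_from_file

            loaded = spec_from_file(spec_path)
            tr = loaded.tr_seconds
            seed_parcel = config.seed_parcel or loaded.parcel_ids[loaded.seed_node]
        else:
            if config.seed_parcel is None:
                raise ValueError("seed_parcel required when no synthetic spec is present")
            seed_parcel = config.seed_parcel
    else:
        raise ValueError("config needs either a synthetic spec or an input_dir")

    config.to_file(out / "config_resolved.json")

    # --- QC ---
    qc_records = []
    excluded_subjects: set[str] = set()
    for (subject, session), (ts, pids, motion, wm, csf) in sorted(sessions.items()):
        rec = pp.motion_exclusion(
            motion, config.max_translation_mm, config.max_rotation_deg,
            subject=subject, session=session, sphere_radius_mm=config.fd_radius_mm,
        )
        qc_records.append(rec)
        if rec.excluded:
            excluded_subjects.add(subject)
    qc_df = pd.DataFrame(
        [
            {
                "subject": r.subject, "session": r.session, "mean_fd": r.mean_fd,
                "max_trans": r.max_translation_mm, "max_rot": r.max_rotation_deg,
                "excluded": r.excluded,
            }
            for r in qc_records
        ]
    )
    qc_df.to_csv(out / "qc.tsv", sep="\t", index=False)
    subjects_all = sorted({s for (s, _) in sessions})
    kept = [s for s in subjects_all if s not in excluded_subjects]
    if not kept:
        raise RuntimeError("no subjects remain after motion QC")

    # --- preprocessing + connectivity ---
    conn_dir = out / "connectivity"
    conn_dir.mkdir(exist_ok=True)
    conns: list[ConnectivityMatrix] = []
    manifest = []
    for (subject, session), (ts, pids, motion, wm, csf) in sorted(sessions.items()):
        if subject in excluded_subjects:
            continue
        cleaned = preprocess_session(
            ts, motion, wm, csf, config, tr, pids, subject, session
        )
        conn = connectivity_from_timeseries(cleaned)
        conns.append(conn)
        fname = f"{subject}_{session}_z.tsv"
        save_matrix(conn, conn_dir / fname)
        manifest.append((subject, session, fname))
    write_manifest(manifest, conn_dir / "manifest.tsv")

    # --- gFC screen ---
    table = gfc_table(conns)
    table.to_csv(out / "gfc_table.tsv", sep="\t", index=False)
    deltas = delta_gfc(*split_sessions(table))
    deltas.to_csv(out / "gfc_deltas.tsv", sep="\t", index=False)
    screen, detected = gfc_change_screen(
        deltas, q=config.q, method=config.fdr_method, family=config.fdr_family
    )
    screen.to_csv(out / "gfc_screen.tsv", sep="\t", index=False)

    # --- fixed positive set + restricted validation ---
    fps = fixed_positive_set(seed_parcel, conns, alpha=config.fixed_set_alpha)
    restricted, rt = restricted_delta_gfc(seed_parcel, fps.members, conns) if fps.members else (
        None, None
    )
    (out / "fixed_positive_set.json").write_text(
        json.dumps(
            {
                "seed": fps.seed, "alpha": fps.alpha, "members": fps.members,
                "restricted_t": None
                if rt is None
                else {"mean": rt.mean, "sd": rt.sd, "t": rt.t, "df": rt.df, "p": rt.p},
            },
            indent=2,
        )
    )

    # --- edge screens ---
    whole = edge_change_test(conns, "whole_brain", q=config.q, method=config.fdr_method)
    whole.to_csv(out / "edges_whole_brain.tsv", sep="\t", index=False)
    seed_tbl = edge_change_test(
        conns, "seed_restricted", seed=seed_parcel, q=config.q, method=config.fdr_method
    )
    seed_tbl.to_csv(out / "edges_seed.tsv", sep="\t", index=False)
    increased = count_increased_edges(conns, seed_parcel)

    # --- associations (only when behavioral data are supplied) ---
    associations: list[dict[str, Any]] = []
    if config.behavior_path is not None:
        brain = _brain_measures(deltas, restricted, seed_parcel, seed_tbl)
        brain.to_csv(out / "brain_measures.tsv", sep="\t", index=False)
        behavior_df = pd.read_csv(config.behavior_path, sep="\t")
        families: Mapping[str, list[list[str]]] = {}
        if config.families_path is not None:
            families = yaml.safe_load(Path(config.families_path).read_text())
        assoc = associate_tables(brain, behavior_df, families, q=config.q,
                                 method=config.fdr_method)
        assoc.to_csv(out / "associations.tsv", sep="\t", index=False)
        associations = assoc.to_dict("records")

    report = RunReport(
        qc=qc_df.to_dict("records"),
        subjects_total=len(subjects_all),
        subjects_excluded=sorted(excluded_subjects),
        parcels=len(conns[0].parcel_ids),
        detected=detected,
        fixed_set_seed=seed_parcel,
        fixed_set_size=len(fps.members),
        restricted_t={} if rt is None else {"mean": rt.mean, "t": rt.t, "p": rt.p},
        seed_edges_significant=[
            (r.i, r.j) for r in seed_tbl.itertuples(index=False) if r.significant
        ],
        whole_brain_edges_significant=int(whole["significant"].sum()),
        increased_seed_edges=increased,
        n_tests={
            "gfc_screen": len(screen),
            "whole_brain_edges": len(whole),
            "seed_edges": len(seed_tbl),
            "associations": len(associations),
        },
        associations=associations,
    )
    (out / "report.json").write_text(report.to_json())
    return report


def _brain_measures(deltas, restricted, seed_parcel, seed_tbl) -> pd.DataFrame:
    """Per-subject brain change measures available for association analyses."""
    seed_rows = deltas[deltas["parcel"] == seed_parcel][["subject", "dgfc_pos"]]
    out = seed_rows.rename(columns={"dgfc_pos": "seed_dgfc_pos"})
    if restricted is not None:
        out = out.merge(
            restricted["delta"].rename("seed_restricted_delta").reset_index(), on="subject"
        )
    return out


def associate_tables(
    brain: pd.DataFrame,
    behavior_df: pd.DataFrame,
    families: Mapping[str, list[list[str]]],
    q: float = 0.05,
    method: str = "by",
) -> pd.DataFrame:
    """Spearman associations between brain and behavioral columns, by family.

    ``families`` maps a family label to a list of [brain_column,
    behavior_column] pairs; FDR adjustment runs within each family.
    """
    merged = brain.merge(behavior_df, on="subject", how="inner")
    results = []
    for family, pairs in families.items():
        for x_col, y_col in pairs:
            results.append(
                bhv.spearman_assoc(
                    merged[x_col], merged[y_col], pair=f"{x_col}~{y_col}", family=family
                )
            )
    if not results:
        return pd.DataFrame(
            columns=["pair", "family", "n", "rho", "p", "q_adj", "significant"]
        )
    return bhv.associate_families(results, q=q, method=method)


# ---------------------------------------------------------------------------
# Replicate studies (power / null calibration)
# ---------------------------------------------------------------------------


def _replicate_seed(base_seed: int, rep: int) -> int:
    return (base_seed * 100_003 + 7919 * rep + 17) % (2**31 - 1)


def gfc_screen_replicates(
    spec: SyntheticSpec,
    n_replicates: int,
    q: float = 0.05,
    method: str = "by",
    family: str = "per-measure",
    base_seed: int = 0,
) -> pd.DataFrame:
    """Run the gFC screen on independent synthetic replicates.

    Each replicate regenerates the dataset with a derived RNG seed, computes
    connectivity on the generated signals and runs the screen.  Returns one
    row per replicate: whether the seed node was detected on the positive-gFC
    change measure, and whether any (parcel, measure) was rejected at all.
    """
    seed_id = spec.parcel_ids[spec.seed_node]
    rows = []
    for rep in range(n_replicates):
        s = replace(spec, rng_seed=_replicate_seed(base_seed, rep))
        dataset = generate_dataset(s)
        conns = connectivity_from_dataset(dataset, preprocessed=spec.nuisance_amplitude > 0)
        deltas = delta_gfc(*split_sessions(gfc_table(conns)))
        _, detected = gfc_change_screen(deltas, q=q, method=method, family=family)
        rows.append(
            {
                "replicate": rep,
                "seed_detected_pos": (seed_id, "gfc_pos") in detected,
                "any_rejection": len(detected) > 0,
            }
        )
    return pd.DataFrame(rows)


def edge_screen_replicates(
    spec: SyntheticSpec,
    n_replicates: int,
    q: float = 0.05,
    method: str = "by",
    base_seed: int = 0,
) -> pd.DataFrame:
    """Planted-edge detection per replicate under both edge-screen scopes."""
    seed_id = spec.parcel_ids[spec.seed_node]
    planted = None
    rows = []
    for rep in range(n_replicates):
        s = replace(spec, rng_seed=_replicate_seed(base_seed, rep))
        dataset = generate_dataset(s)
        conns = connectivity_from_dataset(dataset, preprocessed=spec.nuisance_amplitude > 0)
        planted = dataset.planted
        ids = spec.parcel_ids
        planted_ids = {(ids[i], ids[j]) for (i, j) in planted}
        seed_tbl = edge_change_test(conns, "seed_restricted", seed=seed_id, q=q, method=method)
        whole_tbl = edge_change_test(conns, "whole_brain", q=q, method=method)

        def detected(tbl: pd.DataFrame) -> bool:
            hits = tbl[tbl["significant"]]
            return any((r.i, r.j) in planted_ids for r in hits.itertuples(index=False))

        rows.append(
            {
                "replicate": rep,
                "seed_scope_detected": detected(seed_tbl),
                "whole_brain_detected": detected(whole_tbl),
            }
        )
    return pd.DataFrame(rows)
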