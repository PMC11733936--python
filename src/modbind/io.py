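"""File formats, run configuration and the run pipeline.

Structures are PDB; trajectories are DCD or XTC read against a PDB topology
(frame times always come from the configured interval — trajectory-file
timestamps are unreliable across writers).  Run configuration is YAML,
validated strictly (unknown keys rejected); results are CSV with a fixed
column order and a JSON audit report embedding the config hash and seeds so
any reported number is traceable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Literal, Optional

import MDAnalysis as mda
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .adapter import ToyBackend, build_simulation_spec, plan_replicas
from .analysis import (
    CENSOR_AT_TMAX,
    ReplicaSetResult,
    Trajectory,
    UnbindingEvent,
    analyze_replica_trajectories,
)
from .errors import (
    ConfigValidationError,
    StructureFileError,
    TrajectoryFormatError,
    UnreliableEstimateError,
)
from .model import KoffModel
from .reweight import ReweightingParams
from .structure import BACKBONE_NAMES, StructureModel, make_toy_structure
from .toy import ToyPotential

logger = logging.getLogger("modbind")

RESULT_COLUMNS = [
    "ligand_id", "T_sim", "n_replicas", "n_unbound", "tau_median_ps",
    "quality", "k_scaled", "lambda", "log10_koff_ref",
]


# --------------------------------------------------------------------- structures
def _scan_pdb_lines(path: Path) -> None:
    """Reject malformed ATOM/HETATM records, reporting the line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise StructureFileError(
                        f"{path}: line {lineno}: truncated coordinate record"
                    )
                try:
                    for lo, hi in ((30, 38), (38, 46), (46, 54)):
                        float(line[lo:hi])
                except ValueError:
                    raise StructureFileError(
                        f"{path}: line {lineno}: unparseable coordinates"
                    ) from None


def read_structure(path, ligand_resname: str = "LIG") -> StructureModel:
    """Parse a PDB file into a StructureModel with the named ligand selected."""
    path = Path(path)
    if not path.exists():
        raise StructureFileError(f"structure file not found: {path}")
    _scan_pdb_lines(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    atoms = u.atoms
    names = atoms.names.astype(str)
    try:
        elements = atoms.elements.astype(str)
    except mda.exceptions.NoDataError:
        # PDB convention: element = leading letters of the atom name
        elements = np.array([n.strip("0123456789")[:1].upper() or "C" for n in names])
    try:
        records = atoms.record_types.astype(str)
    except mda.exceptions.NoDataError:
        records = np.full(len(atoms), "ATOM")
    try:
        chains = atoms.chainIDs.astype(str)
    except mda.exceptions.NoDataError:
        chains = np.full(len(atoms), "A")
    resnames = atoms.resnames.astype(str)
    resids = atoms.resids.astype(int)

    ligand = np.flatnonzero(resnames == ligand_resname)
    if ligand.size == 0:
        het = sorted(set(resnames[records == "HETATM"]))
        raise StructureFileError(
            f"no residue named {ligand_resname!r} in {path}; "
            f"HET residues present: {het or 'none'}"
        )
    lig_mask = np.zeros(len(atoms), dtype=bool)
    lig_mask[ligand] = True
    backbone = np.flatnonzero(~lig_mask & np.isin(names, BACKBONE_NAMES))
    return StructureModel(
        serials=atoms.ids.astype(int),
        names=names,
        elements=elements,
        resids=resids,
        resnames=resnames,
        chains=chains,
        record_types=records,
        xyz=atoms.positions.astype(float),
        ligand_selection=ligand,
        protein_backbone=backbone,
    )


def write_structure(structure: StructureModel, path) -> None:
    """Write a StructureModel to PDB (coordinates at PDB's 3-decimal precision)."""
    keys = structure.residue_keys()
    # residue index per atom, preserving file order of residues
    order = pd.unique(keys)
    key_to_res = {k: i for i, k in enumerate(order)}
    resindex = np.array([key_to_res[k] for k in keys])
    n_res = len(order)
    first_atom = [np.flatnonzero(resindex == i)[0] for i in range(n_res)]
    u = mda.Universe.empty(
        structure.n_atoms, n_residues=n_res, atom_resindex=resindex, trajectory=True
    )
    u.add_TopologyAttr("names", structure.names)
    u.add_TopologyAttr("elements", structure.elements)
    u.add_TopologyAttr("record_types", structure.record_types)
    u.add_TopologyAttr("chainIDs", structure.chains)
    u.add_TopologyAttr("resnames", [structure.resnames[i] for i in first_atom])
    u.add_TopologyAttr("resids", [structure.resids[i] for i in first_atom])
    u.atoms.positions = structure.xyz
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


# -------------------------------------------------------------------- trajectories
def read_trajectory(path, structure: StructureModel,
                    frame_interval_ps: float = 10.0) -> Trajectory:
    """Read a DCD/XTC trajectory against the structure's topology.

    Frame times are assigned from ``frame_interval_ps`` starting at 0.
    """
    path = Path(path)
    if not path.exists():
        raise TrajectoryFormatError(f"trajectory file not found: {path}")
    u = mda.Universe.empty(structure.n_atoms, trajectory=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u.load_new(str(path))
            frames = np.array([u.atoms.positions.copy() for _ in u.trajectory])
    except (ValueError, OSError, EOFError) as exc:
        n_file = _probe_n_atoms(path)
        if n_file is not None and n_file != structure.n_atoms:
            raise TrajectoryFormatError(
                f"{path}: trajectory has {n_file} atoms, topology has "
                f"{structure.n_atoms}"
            ) from exc
        raise TrajectoryFormatError(f"{path}: cannot read trajectory: {exc}") from exc
    if frames.shape[0] == 0:
        raise TrajectoryFormatError(f"{path}: trajectory contains no frames")
    times = np.arange(frames.shape[0]) * frame_interval_ps
    return Trajectory(structure, frames, times)


def _probe_n_atoms(path: Path) -> int | None:
    reader_cls = None
    if path.suffix.lower() == ".dcd":
        from MDAnalysis.coordinates.DCD import DCDReader as reader_cls
    elif path.suffix.lower() == ".xtc":
        from MDAnalysis.coordinates.XTC import XTCReader as reader_cls
    if reader_cls is None:
        return None
    try:
        reader = reader_cls(str(path))
    except Exception:
        return None
    try:
        return reader.n_atoms
    finally:
        reader.close()


def write_trajectory(traj: Trajectory, path) -> None:
    """Write trajectory coordinates to DCD/XTC (times are not preserved)."""
    u = mda.Universe.empty(traj.topology.n_atoms, trajectory=True)
    u.dimensions = [999.0, 999.0, 999.0, 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.topology.n_atoms) as w:
            for f in range(traj.n_frames):
                u.atoms.positions = traj.frames[f]
                w.write(u.atoms)


# ------------------------------------------------------------------- configuration
class AnalysisOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cutoff_A: float = 5.0
    persistence_frames: int = Field(default=5, ge=1)
    censoring: Literal["censored_at_tmax", "drop_censored"] = CENSOR_AT_TMAX
    allow_lower_bound: bool = False


class ToyLigandConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    id: str
    barrier_height: float = Field(gt=0)
    well_curvature: float = Field(default=4.0, gt=0)
    barrier_curvature: float = Field(default=4.0, gt=0)


class ToyOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    friction: float = Field(default=1.0, gt=0)
    dt: float = Field(default=0.01, gt=0)
    time_scale_ps: float = Field(default=10.0, gt=0)
    emit: Literal["trajectories", "events"] = "trajectories"
    noise_sigma_A: float = Field(default=0.1, ge=0)
    displacement_A: float = Field(default=8.0, gt=0)
    rotation_deg_per_frame: float = 0.5
    ligands: list[ToyLigandConfig]


class RunConfig(BaseModel):
    """Validated run configuration (unknown keys are rejected)."""

    model_config = ConfigDict(extra="forbid")
    structure: str
    ligand_resname: str = "LIG"
    backend: Literal["toy", "external"] = "toy"
    temperature_K: float = Field(gt=0)
    T_ref_K: float = Field(default=300.0, gt=0)
    total_time_ns: float = Field(gt=0)
    time_step_fs: float = Field(default=2.0, gt=0)
    sigma_A: float = Field(default=3.0, gt=0)
    site_cutoff_A: float = Field(default=6.0, ge=0)
    n_replicas: int = Field(default=32, ge=1)
    base_seed: int = 0
    frame_interval_ps: float = Field(default=10.0, gt=0)
    analysis: AnalysisOptions = AnalysisOptions()
    toy: Optional[ToyOptions] = None
    trajectories: Optional[dict[str, list[str]]] = None
    output_dir: str = "modbind_out"
    log_level: str = "INFO"


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; referenced paths must exist."""
    path = Path(path)
    if not path.exists():
        raise ConfigValidationError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigValidationError(f"{path}: config must be a YAML mapping")
    try:
        cfg = RunConfig(**raw)
    except ValidationError as exc:
        issues = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise ConfigValidationError(f"{path}: {issues}") from None
    base = path.parent
    problems = []
    structure_path = base / cfg.structure if not Path(cfg.structure).is_absolute() else Path(cfg.structure)
    if not structure_path.exists():
        problems.append(f"structure file not found: {cfg.structure}")
    cfg = cfg.model_copy(update={"structure": str(structure_path)})
    if cfg.backend == "toy":
        if cfg.toy is None:
            problems.append("backend 'toy' requires a 'toy' section")
    else:
        if not cfg.trajectories:
            problems.append("backend 'external' requires a 'trajectories' mapping")
        else:
            resolved = {}
            for lig, paths in cfg.trajectories.items():
                resolved[lig] = []
                for p in paths:
                    pp = base / p if not Path(p).is_absolute() else Path(p)
                    if not pp.exists():
                        problems.append(f"trajectory file not found: {p}")
                    resolved[lig].append(str(pp))
            cfg = cfg.model_copy(update={"trajectories": resolved})
    if problems:
        raise ConfigValidationError("; ".join(problems))
    return cfg


def config_hash(cfg: RunConfig) -> str:
    """Stable SHA-256 of the validated configuration."""
    payload = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


# ------------------------------------------------------------------------ pipeline
def run_pipeline(cfg: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Execute plan -> backend -> analysis -> reweighting for every ligand.

    Returns the results table (fixed column order) and the JSON-ready audit
    report.  All randomness flows from ``base_seed``; reruns with the same
    config are bitwise identical.
    """
    structure = read_structure(cfg.structure, cfg.ligand_resname)
    params = ReweightingParams(T_sim=cfg.temperature_K, T_ref=cfg.T_ref_K)
    rows, audits, warn_list = [], {}, []

    ligand_sets = _collect_replica_sets(cfg, structure, warn_list)
    for result in ligand_sets:
        model = KoffModel(result, params, censoring_policy=cfg.analysis.censoring)
        try:
            fit = model.fit(
                allow_lower_bound=cfg.analysis.allow_lower_bound,
                n_boot=200, boot_seed=cfg.base_seed,
            )
            est = fit.estimate
            rows.append({
                "ligand_id": est.ligand_id,
                "T_sim": cfg.temperature_K,
                "n_replicas": result.n_replicas,
                "n_unbound": result.n_unbound,
                "tau_median_ps": est.audit["tau_median_ps"],
                "quality": fit.quality,
                "k_scaled": est.k_scaled_per_ns,
                "lambda": est.lambda_,
                "log10_koff_ref": est.log10_koff_ref,
            })
            audits[est.ligand_id] = dict(est.audit, conf_int_log10=list(fit.conf_int_log10))
        except UnreliableEstimateError as exc:
            warn_list.append(str(exc))
            rows.append({
                "ligand_id": result.ligand_id,
                "T_sim": cfg.temperature_K,
                "n_replicas": result.n_replicas,
                "n_unbound": result.n_unbound,
                "tau_median_ps": np.nan,
                "quality": "LOWER_BOUND",
                "k_scaled": np.nan,
                "lambda": params.lambda_,
                "log10_koff_ref": np.nan,
            })
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    report = {
        "version": __version__,
        "config_sha256": config_hash(cfg),
        "base_seed": cfg.base_seed,
        "T_sim_K": cfg.temperature_K,
        "T_ref_K": cfg.T_ref_K,
        "lambda": params.lambda_,
        "ligands": audits,
        "warnings": warn_list,
    }
    return results, report


def _collect_replica_sets(cfg: RunConfig, structure: StructureModel,
                          warn_list: list) -> list[ReplicaSetResult]:
    sim_cfg = {
        "temperature_K": cfg.temperature_K,
        "total_time_ns": cfg.total_time_ns,
        "time_step_fs": cfg.time_step_fs,
        "sigma_A": cfg.sigma_A,
        "site_cutoff_A": cfg.site_cutoff_A,
        "n_replicas": cfg.n_replicas,
        "base_seed": cfg.base_seed,
        "frame_interval_ps": cfg.frame_interval_ps,
        "T_ref_K": cfg.T_ref_K,
    }
    out = []
    if cfg.backend == "toy":
        for lig_idx, lig in enumerate(cfg.toy.ligands):
            # distinct, reproducible seed block per ligand
            lig_cfg = dict(sim_cfg, base_seed=cfg.base_seed + 10_000 * lig_idx)
            spec = build_simulation_spec(lig_cfg, structure)
            potential = ToyPotential(
                barrier_height=lig.barrier_height,
                well_curvature=lig.well_curvature,
                barrier_curvature=lig.barrier_curvature,
            )
            backend = ToyBackend(
                structure, potential, spec, T_ref_K=cfg.T_ref_K,
                friction=cfg.toy.friction, dt=cfg.toy.dt,
                time_scale_ps=cfg.toy.time_scale_ps,
                noise_sigma_A=cfg.toy.noise_sigma_A,
                displacement_A=cfg.toy.displacement_A,
                rotation_deg_per_frame=cfg.toy.rotation_deg_per_frame,
            )
            t_max_ps = cfg.total_time_ns * 1000.0
            if cfg.toy.emit == "trajectories":
                trajs = []
                for rep in plan_replicas(spec):
                    trajs.append(backend.run(rep))
                result = analyze_replica_trajectories(
                    trajs, lig.id, cfg.temperature_K,
                    cfg.analysis.cutoff_A, cfg.analysis.persistence_frames,
                )
            else:
                events = []
                for rep in plan_replicas(spec):
                    t_ps = backend.escape_time_ps(rep)
                    if t_ps is not None and t_ps > t_max_ps:
                        t_ps = None
                    events.append(UnbindingEvent(rep.index, t_ps, t_max_ps))
                result = ReplicaSetResult(lig.id, cfg.temperature_K, events)
            for e in result.events:
                logger.info(
                    "ligand=%s replica=%d unbind=%s", lig.id, e.replica_id,
                    "CENSORED" if e.censored else f"{e.unbind_time_ps:.1f}ps",
                )
            out.append(result)
    else:
        for lig_id, paths in cfg.trajectories.items():
            trajs = [read_trajectory(p, structure, cfg.frame_interval_ps) for p in paths]
            result = analyze_replica_trajectories(
                trajs, lig_id, cfg.temperature_K,
                cfg.analysis.cutoff_A, cfg.analysis.persistence_frames,
            )
            for e in result.events:
                logger.info(
                    "ligand=%s replica=%d unbind=%s", lig_id, e.replica_id,
                    "CENSORED" if e.censored else f"{e.unbind_time_ps:.1f}ps",
                )
            out.append(result)
    return out


def write_results(results: pd.DataFrame, report: dict, outdir) -> tuple[Path, Path]:
    """Write the results CSV (fixed columns, C-locale numbers) and JSON report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / "results.csv"
    json_path = outdir / "report.json"
    results.to_csv(csv_path, index=False)
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return csv_path, json_path


# ----------------------------------------------------------------- fixture emitters
def generate_screen_table(n: int = 100, n_active: int = 20, seed: int = 0) -> pd.DataFrame:
    """Synthetic ranked-screen table: weak docking signal, strong rescoring signal."""
    rng = np.random.default_rng(seed)
    active = np.zeros(n, dtype=bool)
    active[:n_active] = True
    rng.shuffle(active)
    docking = rng.normal(0.0, 1.0, n) - 0.6 * active
    rescore = rng.normal(0.0, 0.5, n) - 2.0 * active
    return pd.DataFrame({
        "compound_id": [f"cmpd{i:04d}" for i in range(n)],
        "label": np.where(active, "ACTIVE", "DECOY"),
        "docking_score": np.round(docking, 4),
        "modbind_score": np.round(rescore, 4),
        "hit": active.astype(int),
    })


def generate_bench_table(n_targets: int = 8, seed: int = 0,
                         n_singletons: int = 2) -> pd.DataFrame:
    """Synthetic benchmark table with planted per-target correlation.

    Each target's predictions follow its observed log10 k_off up to a
    target-specific affine distortion plus noise; a few binding-mode classes
    and singleton targets are planted for the filtering/normalization paths.
    """
    rng = np.random.default_rng(seed)
    classes = ["", "", "type-1", "type-2", "transition-state"]
    rows = []
    for t in range(n_targets):
        n_lig = 1 if t < n_singletons else int(rng.integers(4, 9))
        slope = rng.uniform(0.6, 1.6)
        intercept = rng.uniform(-1.5, 1.5)
        for j in range(n_lig):
            obs = rng.uniform(-6.0, -1.0)
            pred = slope * obs + intercept + rng.normal(0.0, 0.3)
            rows.append({
                "target_id": f"T{t:02d}",
                "ligand_id": f"T{t:02d}_L{j:02d}",
                "observed": round(obs, 4),
                "predicted": round(pred, 4),
                "binding_mode_class": classes[int(rng.integers(0, len(classes)))],
            })
    return pd.DataFrame(rows)


def emit_fixtures(outdir, seed: int = 0) -> dict[str, Path]:
    """Write the bundled toy inputs: structure, config, trajectory, score tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    structure = make_toy_structure()
    paths = {}

    pdb_path = outdir / "toy.pdb"
    write_structure(structure, pdb_path)
    paths["structure"] = pdb_path

    config = {
        "structure": "toy.pdb",
        "ligand_resname": "LIG",
        "backend": "toy",
        "temperature_K": 900.0,
        "T_ref_K": 300.0,
        "total_time_ns": 1.0,
        "n_replicas": 8,
        "base_seed": seed,
        "frame_interval_ps": 10.0,
        "analysis": {"persistence_frames": 2},
        "toy": {
            "time_scale_ps": 10.0,
            "emit": "trajectories",
            "ligands": [
                {"id": "ligA", "barrier_height": 5.0},
                {"id": "ligB", "barrier_height": 7.0},
            ],
        },
        "output_dir": "toy_out",
    }
    yaml_path = outdir / "toy.yaml"
    with open(yaml_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    paths["config"] = yaml_path

    from .toy import ScriptedTrajectorySpec, make_scripted_trajectory

    scripted = make_scripted_trajectory(
        ScriptedTrajectorySpec(
            n_frames=120, frame_interval_ps=10.0, departure_frame=100,
            recrossing_frames=(50,), rotation_deg_per_frame=1.0,
            noise_sigma_A=0.05, seed=seed,
        ),
        structure,
    )
    dcd_path = outdir / "scripted.dcd"
    write_trajectory(scripted, dcd_path)
    paths["trajectory"] = dcd_path

    screen_path = outdir / "screen_scores.csv"
    generate_screen_table(seed=seed).to_csv(screen_path, index=False)
    paths["screen"] = screen_path

    bench_path = outdir / "bench.csv"
    generate_bench_table(seed=seed).to_csv(bench_path, index=False)
    paths["bench"] = bench_path
    return paths
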