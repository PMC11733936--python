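"""Simulation planning: restraint selection, validated simulation specs, replica
plans, and the backend contract (with the built-in toy backend).

The production protocol restrains protein backbone atoms (harmonic, sigma =
3.0 A read as the positional standard deviation, k = k_B*T_ref/sigma^2 per
coordinate) except for residues with any heavy atom within 6 A of the ligand
pose, runs NVT Langevin dynamics at 600-1000 K with a 2 fs step, and launches
up to 32 replicas with per-replica seeds.  Any engine satisfying the backend
contract (run descriptor in, trajectory with the declared frame count and
interval out) can execute the plan; the toy backend fulfils it exactly and
keeps the whole pipeline testable without an MD engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .analysis import Trajectory
from .errors import ConfigValidationError, InvalidInputError
from .reweight import R_KCAL_PER_MOL_K, T_REF_DEFAULT_K
from .structure import BACKBONE_NAMES, StructureModel
from .toy import (
    LangevinSpec,
    ScriptedTrajectorySpec,
    ToyPotential,
    make_scripted_trajectory,
    simulate_escape,
)

DEFAULT_SIGMA_A = 3.0
DEFAULT_SITE_CUTOFF_A = 6.0
DEFAULT_N_REPLICAS = 32


def select_restrained_atoms(structure: StructureModel,
                            cutoff_A: float = DEFAULT_SITE_CUTOFF_A) -> np.ndarray:
    """Backbone atoms to restrain: all residues without heavy atoms near the ligand.

    A residue is freed (excluded from restraints) when any of its heavy atoms
    lies within ``cutoff_A`` (inclusive) of any ligand heavy atom in the
    input pose; exclusion is residue-granular.  Invariant under rigid motion
    of the whole complex since only internal distances enter.
    """
    if structure.ligand_selection.size == 0:
        raise InvalidInputError("structure has no ligand selection")
    if cutoff_A < 0:
        raise InvalidInputError(f"cutoff must be nonnegative, got {cutoff_A}")
    lig_heavy = structure.ligand_heavy
    if lig_heavy.size == 0:
        raise InvalidInputError("ligand has no heavy atoms")
    keys = structure.residue_keys()
    heavy = structure.heavy_mask
    prot = structure.protein_indices
    prot_heavy = prot[heavy[prot]]
    tree = cKDTree(structure.xyz[lig_heavy])
    dists, _ = tree.query(structure.xyz[prot_heavy])
    near_keys = set(keys[prot_heavy[dists <= cutoff_A]])
    backbone = structure.protein_backbone
    keep = [idx for idx in backbone if keys[idx] not in near_keys]
    return np.array(keep, dtype=int)


@dataclass(frozen=True)
class RestraintSpec:
    """Harmonic positional restraints on the protein backbone away from the site."""

    restrained_atoms: np.ndarray
    sigma_A: float = DEFAULT_SIGMA_A
    binding_site_cutoff_A: float = DEFAULT_SITE_CUTOFF_A
    T_ref_K: float = T_REF_DEFAULT_K

    @property
    def force_constant_kcal_mol_A2(self) -> float:
        """Boltzmann-consistent spring constant k = k_B T_ref / sigma^2 per coordinate."""
        return R_KCAL_PER_MOL_K * self.T_ref_K / self.sigma_A**2


@dataclass(frozen=True)
class SimulationSpec:
    """Fully validated plan for one ligand's replica set."""

    temperature_K: float
    total_time_ns: float
    restraints: RestraintSpec
    time_step_fs: float = 2.0
    thermostat_friction_per_ps: float = 1.0
    ensemble: str = "NVT"
    n_replicas: int = DEFAULT_N_REPLICAS
    base_seed: int = 0
    frame_interval_ps: float = 10.0

    @property
    def n_frames(self) -> int:
        """Saved frames per replica, including the initial frame."""
        return int(round(self.total_time_ns * 1000.0 / self.frame_interval_ps)) + 1


_SPEC_DEFAULTS = {
    "time_step_fs": 2.0,
    "sigma_A": DEFAULT_SIGMA_A,
    "site_cutoff_A": DEFAULT_SITE_CUTOFF_A,
    "n_replicas": DEFAULT_N_REPLICAS,
    "base_seed": 0,
    "frame_interval_ps": 10.0,
    "friction_per_ps": 1.0,
    "T_ref_K": T_REF_DEFAULT_K,
}


def build_simulation_spec(config: dict, structure: StructureModel) -> SimulationSpec:
    """Validate a key-value config and assemble a SimulationSpec.

    ``config`` must supply ``temperature_K`` and ``total_time_ns``; remaining
    keys fall back to protocol defaults (2 fs step, NVT, sigma = 3.0 A,
    6 A site cutoff, 32 replicas).  All offending keys are reported at once.
    """
    cfg = dict(_SPEC_DEFAULTS)
    cfg.update(config)
    problems = []
    for key in ("temperature_K", "total_time_ns"):
        if key not in config:
            problems.append(f"missing required key {key!r}")
    checks = {
        "temperature_K": lambda v: v > 0,
        "total_time_ns": lambda v: v > 0,
        "time_step_fs": lambda v: v > 0,
        "sigma_A": lambda v: v > 0,
        "site_cutoff_A": lambda v: v >= 0,
        "n_replicas": lambda v: int(v) >= 1,
        "frame_interval_ps": lambda v: v > 0,
        "friction_per_ps": lambda v: v > 0,
        "T_ref_K": lambda v: v > 0,
    }
    for key, ok in checks.items():
        if key in cfg:
            try:
                if not ok(cfg[key]):
                    problems.append(f"{key}={cfg[key]!r} out of range")
            except TypeError:
                problems.append(f"{key}={cfg[key]!r} has wrong type")
    if not problems:
        n_steps = cfg["total_time_ns"] * 1000.0 / cfg["frame_interval_ps"]
        if abs(n_steps - round(n_steps)) > 1e-9:
            problems.append(
                "total_time_ns/frame_interval_ps must give an integer frame count"
            )
    if problems:
        raise ConfigValidationError("; ".join(problems))

    restraints = RestraintSpec(
        restrained_atoms=select_restrained_atoms(structure, cfg["site_cutoff_A"]),
        sigma_A=cfg["sigma_A"],
        binding_site_cutoff_A=cfg["site_cutoff_A"],
        T_ref_K=cfg["T_ref_K"],
    )
    return SimulationSpec(
        temperature_K=float(cfg["temperature_K"]),
        total_time_ns=float(cfg["total_time_ns"]),
        restraints=restraints,
        time_step_fs=float(cfg["time_step_fs"]),
        thermostat_friction_per_ps=float(cfg["friction_per_ps"]),
        n_replicas=int(cfg["n_replicas"]),
        base_seed=int(cfg["base_seed"]),
        frame_interval_ps=float(cfg["frame_interval_ps"]),
    )


@dataclass(frozen=True)
class ReplicaRun:
    """Descriptor for one replica: identical physics, unique seed."""

    index: int
    seed: int
    spec: SimulationSpec


def plan_replicas(spec: SimulationSpec) -> list[ReplicaRun]:
    """One descriptor per replica, seed = base_seed + index; order-independent."""
    return [ReplicaRun(i, spec.base_seed + i, spec) for i in range(spec.n_replicas)]


class ToyBackend:
    """Backend that satisfies the MD contract with the toy Langevin simulator.

    A replica's 1D first-passage escape (reduced units, temperature
    ``temperature_K / T_ref_K``) is mapped onto a 3D coordinate trajectory by
    planting the ligand departure at the corresponding frame of a scripted
    trajectory; reduced time maps to ps via ``time_scale_ps``.
    """

    def __init__(self, topology: StructureModel, potential: ToyPotential,
                 spec: SimulationSpec, T_ref_K: float = T_REF_DEFAULT_K,
                 friction: float = 1.0, dt: float = 0.01,
                 time_scale_ps: float = 10.0, noise_sigma_A: float = 0.1,
                 displacement_A: float = 8.0, rotation_deg_per_frame: float = 0.5):
        self.topology = topology
        self.potential = potential
        self.spec = spec
        self.reduced_temperature = spec.temperature_K / T_ref_K
        self.friction = friction
        self.dt = dt
        self.time_scale_ps = time_scale_ps
        self.noise_sigma_A = noise_sigma_A
        self.displacement_A = displacement_A
        self.rotation_deg_per_frame = rotation_deg_per_frame

    def _langevin_spec(self, replica: ReplicaRun) -> LangevinSpec:
        t_max_reduced = self.spec.total_time_ns * 1000.0 / self.time_scale_ps
        return LangevinSpec(
            temperature=self.reduced_temperature,
            t_max=t_max_reduced,
            friction=self.friction,
            dt=self.dt,
            seed=replica.seed,
            n_replicas=1,
        )

    def escape_time_ps(self, replica: ReplicaRun) -> float | None:
        """First-passage time in ps for one replica (None when censored)."""
        sample = simulate_escape(self.potential, self._langevin_spec(replica))[0]
        return None if sample.censored else sample.escape_time * self.time_scale_ps

    def run(self, replica: ReplicaRun) -> Trajectory:
        """Produce the replica's trajectory with the declared frame count/interval."""
        t_ps = self.escape_time_ps(replica)
        spec = self.spec
        n_frames = spec.n_frames
        departure = None
        if t_ps is not None:
            frame = math.ceil(t_ps / spec.frame_interval_ps)
            if frame < n_frames:
                departure = max(frame, 1)
        scripted = ScriptedTrajectorySpec(
            n_frames=n_frames,
            frame_interval_ps=spec.frame_interval_ps,
            departure_frame=departure,
            displacement_A=self.displacement_A,
            rotation_deg_per_frame=self.rotation_deg_per_frame,
            noise_sigma_A=self.noise_sigma_A,
            seed=replica.seed,
        )
        return make_scripted_trajectory(scripted, self.topology)
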