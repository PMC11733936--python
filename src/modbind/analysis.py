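"""Replica-trajectory post-processing: superposition, ligand RMSD, unbinding detection,
and the censored median unbinding-time estimator.

The pipeline mirrors standard unbinding-trajectory analysis: every frame is
rigidly superposed onto frame 1 using the protein atoms only (Kabsch fit),
the ligand heavy-atom RMSD versus frame 1 is computed without any further
fitting, and a ligand is declared unbound at the first frame that begins a
sustained excursion above a distance cutoff (default 5.0 A).  Replicas whose
ligand never leaves within the simulated time are censored; they enter the
median order statistics at t_max, which never biases the median low, and the
estimate is flagged RELIABLE only when strictly more than half the replicas
actually unbound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from MDAnalysis.analysis.align import rotation_matrix as _kabsch_rotation

from .errors import InvalidInputError
from .structure import StructureModel

#: Ligand-RMSD threshold separating bound from unbound configurations (Angstrom).
DEFAULT_CUTOFF_A = 5.0

#: Frames an excursion must persist to count as unbinding (suppresses recrossings).
DEFAULT_PERSISTENCE = 5

RELIABLE = "RELIABLE"
LOWER_BOUND = "LOWER_BOUND"

#: Censoring policies for the median estimator.
CENSOR_AT_TMAX = "censored_at_tmax"
DROP_CENSORED = "drop_censored"


@dataclass
class Trajectory:
    """Coordinate trajectory (Angstrom) tied to a StructureModel topology."""

    topology: StructureModel
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    times_ps: np.ndarray  # (n_frames,)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise InvalidInputError("frames must be (n_frames, n_atoms, 3)")
        if self.frames.shape[0] != self.times_ps.size:
            raise InvalidInputError("times length must match frame count")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise InvalidInputError(
                f"trajectory has {self.frames.shape[1]} atoms, topology has "
                f"{self.topology.n_atoms}"
            )
        if self.times_ps.size == 0:
            raise InvalidInputError("trajectory has no frames")
        if self.times_ps.size > 1:
            dt = np.diff(self.times_ps)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-9):
                raise InvalidInputError("frame times must increase uniformly")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class RmsdSeries:
    """Ligand heavy-atom RMSD versus frame 1, after protein superposition."""

    times_ps: np.ndarray
    values_A: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times_ps", np.asarray(self.times_ps, dtype=float))
        object.__setattr__(self, "values_A", np.asarray(self.values_A, dtype=float))
        if self.times_ps.size != self.values_A.size:
            raise InvalidInputError("times and values must have equal length")


@dataclass(frozen=True)
class UnbindingEvent:
    """First unbinding time of one replica, or a censored lower bound."""

    replica_id: int
    unbind_time_ps: float | None  # None means censored at t_max
    t_max_ps: float

    @property
    def censored(self) -> bool:
        return self.unbind_time_ps is None

    def __post_init__(self) -> None:
        if self.unbind_time_ps is not None:
            if not (0 < self.unbind_time_ps <= self.t_max_ps):
                raise InvalidInputError(
                    f"unbind time {self.unbind_time_ps} outside (0, {self.t_max_ps}]"
                )


@dataclass
class ReplicaSetResult:
    """All replica unbinding events for one ligand at one simulation temperature."""

    ligand_id: str
    T_sim: float
    events: list[UnbindingEvent] = field(default_factory=list)

    @property
    def n_replicas(self) -> int:
        return len(self.events)

    @property
    def n_unbound(self) -> int:
        return sum(not e.censored for e in self.events)

    @property
    def fraction_unbound(self) -> float:
        return self.n_unbound / self.n_replicas if self.events else 0.0


def superpose_to_first_frame(traj: Trajectory, selection=None) -> Trajectory:
    """Rigidly superpose every frame onto frame 1 using the protein selection.

    Uses the least-squares (Kabsch) rotation of the selected atoms; the whole
    system (ligand included) is transformed with the fitted rotation, so
    ligand motion is measured in the protein frame.
    """
    sel = np.asarray(
        traj.topology.protein_indices if selection is None else selection, dtype=int
    )
    if sel.size < 3:
        raise InvalidInputError("superposition selection needs at least 3 atoms")
    ref = traj.frames[0, sel]
    if np.linalg.matrix_rank(ref - ref.mean(axis=0)) < 2:
        raise InvalidInputError("superposition selection is collinear/degenerate")
    ref_centroid = ref.mean(axis=0)
    ref_centered = np.ascontiguousarray(ref - ref_centroid)

    out = np.empty_like(traj.frames)
    out[0] = traj.frames[0]
    for f in range(1, traj.n_frames):
        mob = traj.frames[f, sel]
        mob_centroid = mob.mean(axis=0)
        R, _ = _kabsch_rotation(
            np.ascontiguousarray(mob - mob_centroid), ref_centered
        )
        out[f] = (traj.frames[f] - mob_centroid) @ np.asarray(R).T + ref_centroid
    return Trajectory(traj.topology, out, traj.times_ps)


def ligand_rmsd_series(traj: Trajectory) -> RmsdSeries:
    """Per-frame ligand heavy-atom RMSD versus frame 1 (no ligand fitting).

    The trajectory is expected to be protein-superposed already; the ligand
    is deliberately not refit, so genuine departure shows up in the RMSD.
    """
    lig = traj.topology.ligand_heavy
    if lig.size == 0:
        raise InvalidInputError("ligand selection has no heavy atoms")
    ref = traj.frames[0, lig]
    diff = traj.frames[:, lig, :] - ref[None, :, :]
    values = np.sqrt(np.mean(np.sum(diff * diff, axis=2), axis=1))
    return RmsdSeries(traj.times_ps, values)


def detect_unbinding(series: RmsdSeries, cutoff_A: float = DEFAULT_CUTOFF_A,
                     persistence: int = DEFAULT_PERSISTENCE,
                     replica_id: int = 0) -> UnbindingEvent:
    """Classify bound/unbound along the RMSD series and return the unbinding event.

    The unbinding time is the time of the first frame that begins a run of at
    least ``persistence`` consecutive frames with RMSD > cutoff (earliest
    evidence of a sustained exit).  Transient excursions shorter than the
    persistence window are ignored.  With ``persistence=1`` this reduces to
    the bare single-cutoff rule.  Returns a censored event when no such run
    exists.
    """
    if series.values_A.size == 0:
        raise InvalidInputError("empty RMSD series")
    if persistence < 1:
        raise InvalidInputError(f"persistence must be >= 1, got {persistence}")
    t_max = float(series.times_ps[-1])
    above = series.values_A > cutoff_A
    n = above.size
    if n >= persistence:
        windows = np.lib.stride_tricks.sliding_window_view(above, persistence)
        sustained = np.flatnonzero(windows.all(axis=1))
        if sustained.size:
            return UnbindingEvent(replica_id, float(series.times_ps[sustained[0]]), t_max)
    return UnbindingEvent(replica_id, None, t_max)


def median_unbinding_time(result: ReplicaSetResult,
                          policy: str = CENSOR_AT_TMAX) -> tuple[float, str]:
    """Median unbinding time (ps) across replicas, with a reliability flag.

    Default policy places censored replicas at their t_max in the order
    statistics (dropping them would bias the median low).  The median is
    flagged RELIABLE only when strictly more than half the replicas
    unbound, otherwise it is at best a LOWER_BOUND.
    """
    if not result.events:
        raise InvalidInputError("no replica events")
    quality = RELIABLE if result.n_unbound * 2 > result.n_replicas else LOWER_BOUND
    if policy == CENSOR_AT_TMAX:
        times = [e.t_max_ps if e.censored else e.unbind_time_ps for e in result.events]
    elif policy == DROP_CENSORED:
        times = [e.unbind_time_ps for e in result.events if not e.censored]
        if not times:
            raise InvalidInputError("all replicas censored under drop policy")
    else:
        raise InvalidInputError(f"unknown censoring policy {policy!r}")
    return float(np.median(times)), quality


def analyze_replica_trajectories(trajs, ligand_id: str, T_sim: float,
                                 cutoff_A: float = DEFAULT_CUTOFF_A,
                                 persistence: int = DEFAULT_PERSISTENCE) -> ReplicaSetResult:
    """Superpose, compute ligand RMSD and detect unbinding for each replica trajectory."""
    events = []
    for i, traj in enumerate(trajs):
        fitted = superpose_to_first_frame(traj)
        series = ligand_rmsd_series(fitted)
        events.append(detect_unbinding(series, cutoff_A, persistence, replica_id=i))
    return ReplicaSetResult(ligand_id=ligand_id, T_sim=T_sim, events=events)


@dataclass
class TemperatureScanResult:
    """Outcome of a temperature scan: recommendation plus the full scan table."""

    recommended_K: float | None
    table: "object"  # pandas.DataFrame
    no_solution: bool

    def __bool__(self) -> bool:
        return not self.no_solution


def temperature_scan(results_by_temperature: dict,
                     target_window_ns: tuple[float, float] = (0.0, 4.0),
                     policy: str = CENSOR_AT_TMAX) -> TemperatureScanResult:
    """Pick the lowest temperature giving reliable medians inside a target window.

    ``results_by_temperature`` maps temperature (K) to a list of
    ReplicaSetResult for the reference ligand(s).  A temperature qualifies
    when every reference ligand has a RELIABLE median inside
    ``target_window_ns``; the lowest qualifying temperature wins.
    """
    import pandas as pd

    if len(results_by_temperature) < 2:
        raise InvalidInputError("temperature scan needs results at >= 2 temperatures")
    t_lo, t_hi = target_window_ns
    rows = []
    recommended = None
    for T in sorted(results_by_temperature):
        ok = True
        for res in results_by_temperature[T]:
            tau_ps, quality = median_unbinding_time(res, policy)
            tau_ns = tau_ps / 1000.0
            in_window = t_lo <= tau_ns <= t_hi
            rows.append({
                "temperature_K": T, "ligand_id": res.ligand_id,
                "tau_median_ns": tau_ns, "quality": quality,
                "in_window": in_window,
            })
            ok = ok and quality == RELIABLE and in_window
        if ok and recommended is None:
            recommended = T
    return TemperatureScanResult(
        recommended_K=recommended,
        table=pd.DataFrame(rows),
        no_solution=recommended is None,
    )
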