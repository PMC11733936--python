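"""Desk-scale oracle layer: overdamped Langevin escape from an analytic double well
with a closed-form Kramers rate, and a scripted coordinate-trajectory generator.

The potential is a C1 piecewise-harmonic double well in reduced units
(k_B = 1, energies in k_B*T_ref): a harmonic well of curvature omega_a^2 at
``well_position``, an inverted-harmonic barrier of curvature omega_b^2 and
height ``barrier_height``, mirrored into a second well past the barrier.
Matching value and slope at the join fixes the barrier position, so the
well/barrier geometry is fully determined by (a, dV, omega_a^2, omega_b^2).

In the high-friction (Smoluchowski) regime the escape rate is

    k = sqrt(omega_a^2 * omega_b^2) / (2 pi gamma) * exp(-dV / T),

which serves as the independent closed-form oracle for the Arrhenius
behaviour that temperature-scaled rate reweighting assumes.  The scripted
trajectory generator plants ligand departures at known frames (with optional
rigid-body protein motion and Gaussian noise) so the trajectory-analysis
pipeline can be tested against exact ground truth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation
from scipy import stats

from .analysis import Trajectory
from .errors import InvalidInputError, InvalidParameterError, UnstableTimestepError
from .structure import StructureModel


@dataclass(frozen=True)
class ToyPotential:
    """Piecewise-harmonic double well; barrier position follows from C1 matching."""

    well_position: float = 0.0
    barrier_height: float = 5.0   # dV in k_B T_ref units
    well_curvature: float = 4.0   # omega_a^2
    barrier_curvature: float = 4.0  # omega_b^2

    def __post_init__(self) -> None:
        if self.barrier_height <= 0:
            raise InvalidParameterError(f"barrier height must be positive, got {self.barrier_height}")
        if self.well_curvature <= 0 or self.barrier_curvature <= 0:
            raise InvalidParameterError("curvatures must be positive")

    @property
    def _join(self) -> float:
        """Well-side join between the well and barrier parabolas."""
        wa, wb = self.well_curvature, self.barrier_curvature
        u = math.sqrt(2.0 * self.barrier_height * wb / (wa * (wa + wb)))
        return self.well_position + u

    @property
    def barrier_position(self) -> float:
        wa, wb = self.well_curvature, self.barrier_curvature
        u = self._join - self.well_position
        return self._join + wa * u / wb

    @property
    def second_well_position(self) -> float:
        """Mirror image of the well across the barrier."""
        return 2.0 * self.barrier_position - self.well_position


def double_well_energy(x, pot: ToyPotential) -> np.ndarray:
    """Potential energy; 0 at the well minimum, barrier_height at the barrier top."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("position must be finite")
    a, b = pot.well_position, pot.barrier_position
    xm = pot._join
    xm2 = 2.0 * b - xm
    a2 = pot.second_well_position
    wa, wb = pot.well_curvature, pot.barrier_curvature
    v = np.where(
        x <= xm,
        0.5 * wa * (x - a) ** 2,
        np.where(
            x < xm2,
            pot.barrier_height - 0.5 * wb * (x - b) ** 2,
            0.5 * wa * (x - a2) ** 2,
        ),
    )
    return v if v.shape else float(v)


def double_well_force(x: np.ndarray, pot: ToyPotential) -> np.ndarray:
    """-dV/dx for the piecewise-harmonic double well (vectorized)."""
    a, b = pot.well_position, pot.barrier_position
    xm = pot._join
    xm2 = 2.0 * b - xm
    a2 = pot.second_well_position
    wa, wb = pot.well_curvature, pot.barrier_curvature
    return np.where(
        x <= xm,
        -wa * (x - a),
        np.where(x < xm2, wb * (x - b), -wa * (x - a2)),
    )


def kramers_rate(pot: ToyPotential, temperature: float, friction: float = 1.0) -> float:
    """Closed-form high-friction escape rate over the barrier.

    Valid asymptotically for dV/T >~ 3; a warning is issued below that.
    """
    if temperature <= 0 or friction <= 0:
        raise InvalidParameterError(
            f"temperature and friction must be positive, got T={temperature}, gamma={friction}"
        )
    if pot.barrier_height / temperature < 3.0:
        warnings.warn(
            f"barrier/T = {pot.barrier_height / temperature:.2f} < 3; "
            "Kramers rate may be inaccurate", stacklevel=2,
        )
    omega_a = math.sqrt(pot.well_curvature)
    omega_b = math.sqrt(pot.barrier_curvature)
    return omega_a * omega_b / (2.0 * math.pi * friction) * math.exp(
        -pot.barrier_height / temperature
    )


@dataclass(frozen=True)
class LangevinSpec:
    """Overdamped (Brownian) dynamics settings in reduced units (k_B = 1)."""

    temperature: float
    t_max: float
    friction: float = 1.0
    dt: float = 0.01
    seed: int = 0
    n_replicas: int = 32

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.friction <= 0 or self.t_max <= 0:
            raise InvalidParameterError("temperature, friction and t_max must be positive")
        if self.n_replicas < 1:
            raise InvalidParameterError("n_replicas must be >= 1")
        if not 0 < self.dt < 0.1 / self.friction:
            raise InvalidParameterError(
                f"dt={self.dt} violates the stability bound dt < 0.1/gamma = {0.1 / self.friction}"
            )


@dataclass(frozen=True)
class EscapeSample:
    """First-passage result of one replica; escape_time None means censored at t_max."""

    replica_id: int
    escape_time: float | None
    t_max: float

    @property
    def censored(self) -> bool:
        return self.escape_time is None

    def __post_init__(self) -> None:
        if self.escape_time is not None and not 0 < self.escape_time <= self.t_max:
            raise InvalidInputError(
                f"escape time {self.escape_time} outside (0, {self.t_max}]"
            )


def simulate_escape(pot: ToyPotential, spec: LangevinSpec,
                    margin: float = 1.0) -> list[EscapeSample]:
    """Simulate first-passage escapes with Euler--Maruyama Brownian dynamics.

    All replicas start at the well minimum; escape is absorbing at
    ``barrier_position + margin`` (no re-entry, mirroring the irreversible
    reading of the bound/unbound cutoff).  Replica ``i`` consumes its own
    noise stream seeded ``spec.seed + i``, so results are reproducible and
    independent of how many replicas run alongside.
    """
    # stiffness bound for the explicit integrator on the harmonic pieces
    max_curv = max(pot.well_curvature, pot.barrier_curvature)
    if spec.dt * max_curv / spec.friction > 0.5:
        raise UnstableTimestepError(
            f"dt={spec.dt} too large for curvature {max_curv} (dt*omega^2/gamma > 0.5)"
        )
    x_abs = pot.barrier_position + margin
    n = spec.n_replicas
    rngs = [np.random.default_rng(spec.seed + i) for i in range(n)]
    sigma = math.sqrt(2.0 * spec.temperature * spec.dt / spec.friction)
    inv_gamma_dt = spec.dt / spec.friction
    total_steps = int(round(spec.t_max / spec.dt))
    block = 512

    x = np.full(n, float(pot.well_position))
    escape = np.full(n, np.nan)
    active = np.arange(n)
    step = 0
    while active.size and step < total_steps:
        m = min(block, total_steps - step)
        noise = np.empty((active.size, m))
        for row, idx in enumerate(active):
            noise[row] = rngs[idx].standard_normal(m)
        xa = x[active].copy()
        done = np.zeros(active.size, dtype=bool)
        for k in range(m):
            xa += double_well_force(xa, pot) * inv_gamma_dt + sigma * noise[:, k]
            newly = (~done) & (xa >= x_abs)
            if newly.any():
                escape[active[newly]] = (step + k + 1) * spec.dt
                done |= newly
                np.minimum(xa, x_abs, out=xa)  # park absorbed walkers
        x[active] = xa
        active = active[~done]
        step += m

    return [
        EscapeSample(i, None if math.isnan(escape[i]) else float(escape[i]), spec.t_max)
        for i in range(n)
    ]


def median_escape_time(samples, censored_value: str = "t_max") -> float:
    """Median escape time with censored replicas entered at t_max."""
    if not samples:
        raise InvalidInputError("no escape samples")
    times = [s.t_max if s.censored else s.escape_time for s in samples]
    return float(np.median(times))


def arrhenius_fit(temperatures, median_times) -> tuple[float, float, float]:
    """Fit log(median escape time) against 1/T; returns (slope, intercept, r_squared).

    Linearity of this plot (slope = barrier height) is the Arrhenius property
    that temperature-scaled reweighting relies on.
    """
    T = np.asarray(temperatures, dtype=float)
    tau = np.asarray(median_times, dtype=float)
    if T.size < 2:
        raise InvalidInputError("need >= 2 temperatures")
    res = stats.linregress(1.0 / T, np.log(tau))
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def exponential_qq_r2(times) -> float:
    """R^2 of a QQ plot of escape times against exponential quantiles.

    Values near 1 indicate the first-passage distribution is exponential,
    as expected for rare escapes over a high barrier.
    """
    t = np.sort(np.asarray(times, dtype=float))
    n = t.size
    if n < 5:
        raise InvalidInputError("need >= 5 samples")
    q = -np.log(1.0 - (np.arange(1, n + 1) - 0.5) / n)
    r = np.corrcoef(q, t)[0, 1]
    return float(r * r)


@dataclass(frozen=True)
class ScriptedTrajectorySpec:
    """Recipe for a synthetic trajectory with a planted ligand departure.

    The ligand is displaced by ``displacement_A`` from ``departure_frame``
    onward (permanently) and at each frame in ``recrossing_frames``
    (transiently, one frame each).  All atoms additionally undergo a scripted
    rigid rotation/translation per frame plus Gaussian noise of
    ``noise_sigma_A`` -- motion the protein superposition must remove.
    """

    n_frames: int
    frame_interval_ps: float = 10.0
    departure_frame: int | None = None
    recrossing_frames: tuple = ()
    displacement_A: float = 8.0
    rotation_deg_per_frame: float = 0.0
    translation_A_per_frame: tuple = (0.0, 0.0, 0.0)
    noise_sigma_A: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise InvalidParameterError("need at least 2 frames")
        if self.departure_frame is not None and not (
            1 <= self.departure_frame < self.n_frames
        ):
            raise InvalidInputError(
                f"departure_frame {self.departure_frame} outside [1, {self.n_frames})"
            )
        for f in self.recrossing_frames:
            if not 1 <= f < self.n_frames:
                raise InvalidInputError(f"recrossing frame {f} outside [1, {self.n_frames})")
            if self.departure_frame is not None and f >= self.departure_frame:
                raise InvalidInputError(
                    f"recrossing frame {f} must precede departure_frame {self.departure_frame}"
                )


def make_scripted_trajectory(spec: ScriptedTrajectorySpec,
                             topology: StructureModel) -> Trajectory:
    """Generate a trajectory whose ligand departs at exactly the scripted frame.

    With zero noise the post-superposition ligand RMSD equals
    ``displacement_A`` at displaced frames and 0 elsewhere, giving exact
    ground truth for the detection pipeline.
    """
    if topology.ligand_selection.size == 0:
        raise InvalidInputError("topology has no ligand atoms")
    rng = np.random.default_rng(spec.seed)
    base = topology.xyz
    lig = topology.ligand_selection
    prot = topology.protein_indices
    # displacement direction: away from the protein centre through the ligand
    direction = base[lig].mean(axis=0) - base[prot].mean(axis=0)
    norm = np.linalg.norm(direction)
    direction = direction / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])

    recross = set(spec.recrossing_frames)
    translation = np.asarray(spec.translation_A_per_frame, dtype=float)
    frames = np.empty((spec.n_frames, topology.n_atoms, 3))
    for f in range(spec.n_frames):
        coords = base.copy()
        displaced = (
            spec.departure_frame is not None and f >= spec.departure_frame
        ) or f in recross
        if displaced:
            coords[lig] += spec.displacement_A * direction
        rot = Rotation.from_euler("z", f * spec.rotation_deg_per_frame, degrees=True)
        coords = rot.apply(coords) + f * translation
        if spec.noise_sigma_A > 0:
            coords += rng.normal(0.0, spec.noise_sigma_A, coords.shape)
        frames[f] = coords
    times = np.arange(spec.n_frames) * spec.frame_interval_ps
    return Trajectory(topology, frames, times)
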