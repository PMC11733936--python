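"""Population- and rate-reweighting across temperature scaling, plus thermodynamic conversions.

Running dynamics at a scaled temperature ``T_sim = lambda * T_ref`` flattens the
free-energy landscape: Boltzmann weights observed on the scaled surface relate
to the unscaled ones through an element-wise power ``lambda`` followed by
renormalization.  The same scaling applied on the log-rate scale,

    log10 k(T_ref) = lambda * log10 k(T_sim) + c,

carries a rate measured in an accelerated run back to the reference
temperature up to an additive constant ``c`` that cancels in relative
comparisons and is absorbed by normalization onto an experimental range.

Conversions between K_d, on/off rates and binding free energy
(``dG = R T ln K_d``, ``K_d = k_off / k_on``) live here as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateRangeError, InvalidInputError, InvalidParameterError

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL_PER_MOL_K = 1.987e-3

#: Temperature used for K_d <-> dG conversions (standard assay conditions).
DG_TEMPERATURE_K = 298.0

#: Reference temperature for kinetic reweighting (room temperature).
T_REF_DEFAULT_K = 300.0

#: Median of a unit-rate exponential distribution; k = LN2 / tau_median.
LN2 = math.log(2.0)


@dataclass(frozen=True)
class ReweightingParams:
    """Scaling parameters connecting a high-temperature run to the reference.

    Parameters
    ----------
    T_sim : float
        Simulation temperature in K (or reduced units, as long as the
        ratio to ``T_ref`` is meaningful).
    T_ref : float
        Reference temperature, default 300 K.
    offset_c : float
        Additive constant on the log10-rate scale.  Defaults to 0 and is
        absorbed by :func:`normalize_to_reference`.
    """

    T_sim: float
    T_ref: float = T_REF_DEFAULT_K
    offset_c: float = 0.0

    def __post_init__(self) -> None:
        if not (self.T_sim > 0 and self.T_ref > 0):
            raise InvalidParameterError(
                f"temperatures must be positive, got T_sim={self.T_sim}, T_ref={self.T_ref}"
            )

    @property
    def lambda_(self) -> float:
        """Dimensionless scaling factor T_sim / T_ref."""
        return self.T_sim / self.T_ref


@dataclass(frozen=True)
class PopulationEstimate:
    """State labels with a normalized probability vector."""

    state_labels: tuple
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if len(self.state_labels) != p.size:
            raise InvalidInputError("state_labels and probs must have equal length")
        if np.any(p < 0):
            raise InvalidInputError("probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise InvalidInputError(f"probabilities must sum to 1, got {p.sum()!r}")


@dataclass(frozen=True)
class RateEstimate:
    """A reweighted, relative dissociation-rate estimate for one ligand."""

    ligand_id: str
    tau_median_ns: float
    k_scaled_per_ns: float
    log10_koff_ref: float
    lambda_: float
    offset_c: float = 0.0
    normalized: bool = False
    audit: dict = field(default_factory=dict)


@dataclass(frozen=True)
class AffinityRecord:
    """Equilibrium/kinetic constants for one ligand; K_d = k_off / k_on must hold."""

    ligand_id: str
    kd_M: float
    kon_per_M_s: float | None = None
    koff_per_s: float | None = None
    dg_kcal_per_mol: float | None = None
    temperature_K: float = DG_TEMPERATURE_K

    def __post_init__(self) -> None:
        if not self.kd_M > 0:
            raise InvalidParameterError(f"kd must be positive, got {self.kd_M}")
        if self.kon_per_M_s is not None and self.koff_per_s is not None:
            implied = self.koff_per_s / self.kon_per_M_s
            if abs(implied - self.kd_M) > 1e-9 * abs(self.kd_M):
                raise InvalidInputError(
                    f"kd={self.kd_M} inconsistent with koff/kon={implied}"
                )


def scaling_factor(T_sim: float, T_ref: float = T_REF_DEFAULT_K) -> float:
    """Return the dimensionless scaling factor lambda = T_sim / T_ref."""
    if not (T_sim > 0 and T_ref > 0):
        raise InvalidParameterError(
            f"temperatures must be positive, got T_sim={T_sim}, T_ref={T_ref}"
        )
    return T_sim / T_ref


def reweight_population(p_scaled, lambda_: float) -> np.ndarray:
    """Recover unscaled Boltzmann populations from scaled-run populations.

    Each probability is raised to the power ``lambda_`` and the vector is
    renormalized.  With ``lambda_ = T_sim / T_ref`` this maps populations
    observed on the scaled landscape back to the reference temperature.
    """
    p = np.asarray(p_scaled, dtype=float)
    if not lambda_ > 0:
        raise InvalidParameterError(f"lambda must be positive, got {lambda_}")
    if p.size == 0 or np.any(p < 0) or not np.all(np.isfinite(p)):
        raise InvalidInputError("populations must be finite and nonnegative")
    total = p.sum()
    if total <= 0:
        raise InvalidInputError("population vector must have positive mass")
    w = (p / total) ** lambda_
    return w / w.sum()


def reweight_log_rate(log10_k_scaled: float, params: ReweightingParams) -> float:
    """Map a log10 rate at T_sim onto the reference temperature scale.

    Strictly increasing in its input for any lambda > 0, so the rank
    order of a ligand set is preserved by reweighting.
    """
    if not np.isfinite(log10_k_scaled):
        raise InvalidInputError(f"log10 rate must be finite, got {log10_k_scaled}")
    return params.lambda_ * float(log10_k_scaled) + params.offset_c


def rate_from_median_time(tau_median_ns: float, convention: float = LN2) -> float:
    """Convert a median first-passage time (ns) into a rate (ns^-1).

    Uses k = ln(2)/tau, the exact relation for an exponential first-passage
    distribution.  Any constant convention cancels in relative rates and is
    absorbed by the normalization offset.
    """
    if tau_median_ns is None or not np.isfinite(tau_median_ns) or tau_median_ns <= 0:
        raise InvalidInputError(
            f"median unbinding time must be positive and finite, got {tau_median_ns}"
        )
    return convention / float(tau_median_ns)


def dg_from_kd(kd_M: float, temperature_K: float = DG_TEMPERATURE_K) -> float:
    """Binding free energy (kcal/mol) from K_d (M): dG = R T ln K_d (1 M standard state)."""
    if not kd_M > 0:
        raise InvalidInputError(f"kd must be positive, got {kd_M}")
    if not temperature_K > 0:
        raise InvalidParameterError(f"temperature must be positive, got {temperature_K}")
    return R_KCAL_PER_MOL_K * temperature_K * math.log(kd_M)


def kd_from_dg(dg_kcal_per_mol: float, temperature_K: float = DG_TEMPERATURE_K) -> float:
    """Inverse of :func:`dg_from_kd`: K_d = exp(dG / (R T))."""
    if not temperature_K > 0:
        raise InvalidParameterError(f"temperature must be positive, got {temperature_K}")
    return math.exp(dg_kcal_per_mol / (R_KCAL_PER_MOL_K * temperature_K))


def kd_from_rates(koff_per_s: float, kon_per_M_s: float) -> float:
    """K_d (M) from kinetic constants: K_d = k_off / k_on."""
    if not (koff_per_s > 0 and kon_per_M_s > 0):
        raise InvalidInputError(
            f"rates must be positive, got koff={koff_per_s}, kon={kon_per_M_s}"
        )
    return koff_per_s / kon_per_M_s


def normalize_to_reference(pred, ref_min: float, ref_max: float) -> np.ndarray:
    """Affinely map predicted scores onto a reference [ref_min, ref_max] range.

    The minimum of ``pred`` maps to ``ref_min`` and the maximum to
    ``ref_max``; rank order is unchanged.  This is the step that anchors
    relative predictions to known experimental free-energy/rate ranges.
    """
    x = np.asarray(pred, dtype=float)
    if x.size < 2:
        raise InvalidInputError("need at least two values to normalize")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("scores must be finite")
    if not ref_max > ref_min:
        raise InvalidParameterError(f"ref_max must exceed ref_min, got [{ref_min}, {ref_max}]")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateRangeError("cannot normalize a constant score vector")
    return ref_min + (x - lo) * (ref_max - ref_min) / (hi - lo)
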