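"""Model/Results interface for k_off estimation.

`KoffModel` is built from replica unbinding data (trajectories, detected
events, or a toy escape simulation); `fit()` runs the censored-median
estimator, converts the median first-passage time into a rate and reweights
it to the reference temperature, returning a `KoffResults` with the
estimate, bootstrap uncertainty, diagnostics and a `summary()` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import analysis as _an
from . import reweight as _rw
from .analysis import (
    CENSOR_AT_TMAX,
    LOWER_BOUND,
    ReplicaSetResult,
    UnbindingEvent,
    analyze_replica_trajectories,
    median_unbinding_time,
)
from .errors import InvalidInputError, UnreliableEstimateError
from .reweight import RateEstimate, ReweightingParams


class KoffModel:
    """Relative k_off estimator for one ligand from replica unbinding data.

    Parameters
    ----------
    data : ReplicaSetResult
        Per-replica first-unbinding times (possibly censored).
    params : ReweightingParams
        Temperature scaling connecting the simulation to the reference.
    censoring_policy : str
        How censored replicas enter the median (default: at t_max).
    """

    def __init__(self, data: ReplicaSetResult, params: ReweightingParams,
                 censoring_policy: str = CENSOR_AT_TMAX,
                 rate_convention: float = _rw.LN2):
        if not data.events:
            raise InvalidInputError("replica set has no events")
        self.data = data
        self.params = params
        self.censoring_policy = censoring_policy
        self.rate_convention = rate_convention

    # ---------------------------------------------------------------- builders
    @classmethod
    def from_events(cls, times_ps, t_max_ps: float, ligand_id: str,
                    T_sim: float, T_ref: float = _rw.T_REF_DEFAULT_K,
                    **kwargs) -> "KoffModel":
        """Build from raw unbinding times (ps); None entries are censored."""
        events = [
            UnbindingEvent(i, None if t is None else float(t), float(t_max_ps))
            for i, t in enumerate(times_ps)
        ]
        data = ReplicaSetResult(ligand_id=ligand_id, T_sim=T_sim, events=events)
        return cls(data, ReweightingParams(T_sim=T_sim, T_ref=T_ref), **kwargs)

    @classmethod
    def from_trajectories(cls, trajs, ligand_id: str, T_sim: float,
                          T_ref: float = _rw.T_REF_DEFAULT_K,
                          cutoff_A: float = _an.DEFAULT_CUTOFF_A,
                          persistence: int = _an.DEFAULT_PERSISTENCE,
                          **kwargs) -> "KoffModel":
        """Build by running the full superposition/RMSD/detection pipeline."""
        data = analyze_replica_trajectories(trajs, ligand_id, T_sim, cutoff_A, persistence)
        return cls(data, ReweightingParams(T_sim=T_sim, T_ref=T_ref), **kwargs)

    @classmethod
    def from_toy_escape(cls, potential, langevin_spec, ligand_id: str = "toy",
                        T_ref: float = 1.0, time_scale_ps: float = 1.0,
                        **kwargs) -> "KoffModel":
        """Simulate toy double-well escapes and build the model from them.

        Reduced temperature plays the role of T_sim with T_ref in the same
        reduced units (default 1), and reduced time maps to ps via
        ``time_scale_ps``.
        """
        from .toy import simulate_escape

        samples = simulate_escape(potential, langevin_spec)
        times = [None if s.censored else s.escape_time * time_scale_ps for s in samples]
        return cls.from_events(
            times, langevin_spec.t_max * time_scale_ps, ligand_id,
            T_sim=langevin_spec.temperature, T_ref=T_ref, **kwargs,
        )

    # -------------------------------------------------------------------- fit
    def fit(self, allow_lower_bound: bool = False, n_boot: int = 500,
            boot_seed: int = 0) -> "KoffResults":
        """Estimate the reweighted log10 k_off and its bootstrap uncertainty."""
        tau_ps, quality = median_unbinding_time(self.data, self.censoring_policy)
        if quality == LOWER_BOUND and not allow_lower_bound:
            raise UnreliableEstimateError(
                f"median for {self.data.ligand_id!r} is only a lower bound "
                f"({self.data.n_unbound}/{self.data.n_replicas} replicas unbound); "
                "raise the simulation temperature or extend t_max, or pass "
                "allow_lower_bound=True to proceed anyway"
            )
        log10_ref, k_scaled = self._log10_ref_from_tau(tau_ps)
        conf_int = self._bootstrap_ci(n_boot, boot_seed) if n_boot else (np.nan, np.nan)
        estimate = RateEstimate(
            ligand_id=self.data.ligand_id,
            tau_median_ns=tau_ps / 1000.0,
            k_scaled_per_ns=k_scaled,
            log10_koff_ref=log10_ref,
            lambda_=self.params.lambda_,
            offset_c=self.params.offset_c,
            audit={
                "tau_median_ps": tau_ps,
                "quality": quality,
                "n_replicas": self.data.n_replicas,
                "n_unbound": self.data.n_unbound,
                "censoring_policy": self.censoring_policy,
                "T_sim": self.params.T_sim,
                "T_ref": self.params.T_ref,
                "rate_convention": self.rate_convention,
            },
        )
        return KoffResults(self, estimate, quality, conf_int)

    def _log10_ref_from_tau(self, tau_ps: float) -> tuple[float, float]:
        k_scaled = _rw.rate_from_median_time(tau_ps / 1000.0, self.rate_convention)
        log10_ref = _rw.reweight_log_rate(np.log10(k_scaled), self.params)
        return log10_ref, k_scaled

    def _bootstrap_ci(self, n_boot: int, seed: int,
                      level: float = 0.95) -> tuple[float, float]:
        """Percentile bootstrap over replicas of the reweighted log10 k_off."""
        rng = np.random.default_rng(seed)
        events = self.data.events
        n = len(events)
        values = np.empty(n_boot)
        for b in range(n_boot):
            resampled = [events[j] for j in rng.integers(0, n, size=n)]
            subset = ReplicaSetResult(self.data.ligand_id, self.data.T_sim, resampled)
            tau_ps, _ = median_unbinding_time(subset, self.censoring_policy)
            values[b] = self._log10_ref_from_tau(tau_ps)[0]
        alpha = (1.0 - level) / 2.0
        return (
            float(np.quantile(values, alpha)),
            float(np.quantile(values, 1.0 - alpha)),
        )


@dataclass
class KoffResults:
    """Fitted k_off estimate with uncertainty and audit trail."""

    model: KoffModel
    estimate: RateEstimate
    quality: str
    conf_int_log10: tuple[float, float]

    @property
    def log10_koff_ref(self) -> float:
        return self.estimate.log10_koff_ref

    @property
    def tau_median_ps(self) -> float:
        return self.estimate.audit["tau_median_ps"]

    def events_frame(self) -> pd.DataFrame:
        """Per-replica unbinding table."""
        return pd.DataFrame(
            {
                "replica_id": [e.replica_id for e in self.model.data.events],
                "unbind_time_ps": [e.unbind_time_ps for e in self.model.data.events],
                "censored": [e.censored for e in self.model.data.events],
                "t_max_ps": [e.t_max_ps for e in self.model.data.events],
            }
        )

    def summary(self) -> str:
        est, d = self.estimate, self.model.data
        lo, hi = self.conf_int_log10
        lines = [
            "k_off estimate (temperature-scaled replicas, censored median)",
            "=" * 62,
            f"ligand:                  {est.ligand_id}",
            f"T_sim / T_ref:           {self.model.params.T_sim:g} / {self.model.params.T_ref:g}"
            f"   (lambda = {est.lambda_:g})",
            f"replicas (unbound):      {d.n_replicas} ({d.n_unbound})",
            f"tau_median:              {self.tau_median_ps:.6g} ps   [{self.quality}]",
            f"k at T_sim:              {est.k_scaled_per_ns:.6g} ns^-1",
            f"log10 k_off at T_ref:    {est.log10_koff_ref:.4f}  (relative; offset c = {est.offset_c:g})",
            f"95% bootstrap CI:        [{lo:.4f}, {hi:.4f}]",
            "=" * 62,
        ]
        return "\n".join(lines)

    def plot_escape_times(self, ax=None):
        """Strip plot of replica unbinding times with the median marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3))
        df = self.events_frame()
        times = df["unbind_time_ps"].fillna(df["t_max_ps"])
        colors = np.where(df["censored"], "tab:red", "tab:blue")
        ax.scatter(times, np.arange(len(df)), c=colors, s=18)
        ax.axvline(self.tau_median_ps, color="k", ls="--", label="median")
        ax.set_xlabel("unbinding time (ps)")
        ax.set_ylabel("replica")
        ax.legend(frameon=False)
        return ax


def estimate_koff(result: ReplicaSetResult, params: ReweightingParams,
                  policy: str = CENSOR_AT_TMAX,
                  allow_lower_bound: bool = False) -> RateEstimate:
    """Functional wrapper: replica set -> reweighted RateEstimate.

    Composes the censored median, the exponential-median rate convention and
    log-rate reweighting; all intermediates are recorded in the estimate's
    audit dict.  Refuses lower-bound medians unless explicitly allowed.
    """
    model = KoffModel(result, params, censoring_policy=policy)
    return model.fit(allow_lower_bound=allow_lower_bound, n_boot=0).estimate
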