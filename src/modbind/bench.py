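"""Benchmark statistics for log-scale kinetic/affinity predictions.

Covers the standard scatter-plot metrics (R^2 as squared Pearson r, RMSE,
MUE), per-target min-max range normalization that compensates for
target-specific dynamic ranges, binding-mode-class record filtering (e.g.
removing type-1/type-2 kinase inhibitors or transition-state-directed
inhibitors before correlating k_off with K_d), and error-band summaries
(fraction of predictions within 1 and 2 log units).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError


@dataclass(frozen=True)
class BenchmarkRecord:
    """One observed/predicted pair on a shared log scale."""

    target_id: str
    ligand_id: str
    observed: float
    predicted: float
    scale: str = "log10_koff"
    binding_mode_class: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.observed) and np.isfinite(self.predicted)):
            raise InvalidInputError("observed/predicted must be finite")


@dataclass(frozen=True)
class FilterRules:
    """Which binding-mode classes to exclude; optionally drop singleton targets."""

    excluded_mode_classes: frozenset = field(default_factory=frozenset)
    drop_singleton_targets: bool = False


class RegressionMetrics(NamedTuple):
    r_squared: float
    rmse: float
    mue: float
    n: int


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.reset_index(drop=True)
    return pd.DataFrame(
        {
            "target_id": [r.target_id for r in records],
            "ligand_id": [r.ligand_id for r in records],
            "observed": [r.observed for r in records],
            "predicted": [r.predicted for r in records],
            "binding_mode_class": [r.binding_mode_class for r in records],
        }
    )


def regression_metrics(records) -> RegressionMetrics:
    """R^2 (squared Pearson correlation), RMSE and MUE of predicted vs observed."""
    df = _as_frame(records)
    obs = df["observed"].to_numpy(dtype=float)
    pred = df["predicted"].to_numpy(dtype=float)
    if obs.size < 3:
        raise InvalidInputError(f"need >= 3 records, got {obs.size}")
    if np.ptp(obs) == 0:
        raise InvalidInputError("observed values are constant; R^2 undefined")
    if np.ptp(pred) == 0:
        r2 = float("nan")
    else:
        r2 = float(stats.pearsonr(obs, pred).statistic ** 2)
    err = pred - obs
    return RegressionMetrics(
        r_squared=r2,
        rmse=float(np.sqrt(np.mean(err**2))),
        mue=float(np.mean(np.abs(err))),
        n=int(obs.size),
    )


def per_target_range_normalize(records, drop_singleton_targets: bool = False
                               ) -> tuple[pd.DataFrame, int]:
    """Affinely map each target's predictions onto its observed min/max range.

    Compensates for per-target dynamic-range differences before pooling
    targets; within-target rank order is unchanged.  Targets whose observed
    or predicted values cannot span a range (fewer than 2 distinct values)
    raise, unless ``drop_singleton_targets`` is set, in which case they are
    removed and counted.  Returns (normalized records, n_targets_dropped).
    """
    df = _as_frame(records)
    out, dropped = [], 0
    for target, grp in df.groupby("target_id", sort=False):
        obs = grp["observed"].to_numpy(dtype=float)
        pred = grp["predicted"].to_numpy(dtype=float)
        degenerate = np.unique(obs).size < 2 or np.unique(pred).size < 2
        if degenerate:
            if drop_singleton_targets:
                dropped += 1
                continue
            raise InvalidInputError(
                f"target {target!r} has no usable range "
                "(set drop_singleton_targets=True to remove such targets)"
            )
        mapped = obs.min() + (pred - pred.min()) * (obs.max() - obs.min()) / (
            pred.max() - pred.min()
        )
        grp = grp.copy()
        grp["predicted"] = mapped
        out.append(grp)
    if not out:
        raise InvalidInputError("no targets left after dropping degenerate groups")
    return pd.concat(out, ignore_index=True), dropped


def filter_records(records, rules: FilterRules) -> tuple[pd.DataFrame, dict]:
    """Drop records whose binding-mode class is excluded; log counts per class."""
    df = _as_frame(records)
    removal_log = {}
    keep = np.ones(len(df), dtype=bool)
    for cls in sorted(rules.excluded_mode_classes):
        hit = (df["binding_mode_class"] == cls).to_numpy()
        removal_log[cls] = int(hit.sum())
        keep &= ~hit
    return df[keep].reset_index(drop=True), removal_log


def error_band_fractions(records, bands=(1.0, 2.0)) -> list[float]:
    """Fraction of records with |predicted - observed| <= band, per band width."""
    df = _as_frame(records)
    if len(df) == 0:
        raise InvalidInputError("no records")
    err = np.abs(df["predicted"].to_numpy(dtype=float) - df["observed"].to_numpy(dtype=float))
    fractions = []
    for band in bands:
        if band < 0:
            raise InvalidInputError(f"band width must be nonnegative, got {band}")
        fractions.append(float(np.mean(err <= band)))
    return fractions


def benchmark_from_csv(path) -> pd.DataFrame:
    """Read a benchmark table (target_id, ligand_id, observed, predicted[, binding_mode_class])."""
    df = pd.read_csv(path)
    required = {"target_id", "ligand_id", "observed", "predicted"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"benchmark CSV missing columns: {sorted(missing)}")
    if "binding_mode_class" not in df.columns:
        df["binding_mode_class"] = ""
    return df
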