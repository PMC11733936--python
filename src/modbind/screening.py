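"""Virtual-screening analytics: enrichment factors, enrichment/ROC curves and
hit-rate binning for evaluating re-ranking of docked libraries.

Score direction is always explicit: docking scores are conventionally lower
= better, and so is a relative log10 k_off score when slow dissociation is
the goal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .errors import InvalidInputError

ACTIVE = "ACTIVE"
DECOY = "DECOY"

LOWER = "lower"   # lower score = better (docking convention)
HIGHER = "higher"


@dataclass(frozen=True)
class ScreenRecord:
    """One screened compound with activity label and score(s)."""

    compound_id: str
    label: str
    docking_score: float | None = None
    modbind_score: float | None = None

    def __post_init__(self) -> None:
        if self.label not in (ACTIVE, DECOY):
            raise InvalidInputError(f"label must be ACTIVE or DECOY, got {self.label!r}")
        if self.docking_score is None and self.modbind_score is None:
            raise InvalidInputError("at least one score must be present")


@dataclass(frozen=True)
class EnrichmentInput:
    """Counts entering EF = (a/n)/(A/N)."""

    a: int  # actives found in the sample
    n: int  # sample size
    A: int  # total actives
    N: int  # total ligands

    def __post_init__(self) -> None:
        if not (0 < self.n <= self.N and 0 < self.A <= self.N):
            raise InvalidInputError(f"invalid sizes n={self.n}, A={self.A}, N={self.N}")
        if not 0 <= self.a <= min(self.n, self.A):
            raise InvalidInputError(f"a={self.a} outside [0, min(n, A)]")


@dataclass(frozen=True)
class EnrichmentCurve:
    """Cumulative fraction of actives found versus fraction of library screened."""

    fraction_screened: np.ndarray
    fraction_actives_found: np.ndarray
    auc: float
    n_ties: int = 0

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        ax.plot(self.fraction_screened, self.fraction_actives_found, **kwargs)
        ax.plot([0, 1], [0, 1], "k:", lw=1)
        ax.set_xlabel("fraction screened")
        ax.set_ylabel("fraction of actives found")
        return ax


def enrichment_factor(inp: EnrichmentInput) -> float:
    """EF = (a/n)/(A/N): actives recovered relative to random expectation."""
    return (inp.a / inp.n) / (inp.A / inp.N)


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.reset_index(drop=True)
    return pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "label": [r.label for r in records],
            "docking_score": [r.docking_score for r in records],
            "modbind_score": [r.modbind_score for r in records],
        }
    )


def _ranked(records, score_field: str, direction: str) -> pd.DataFrame:
    df = _as_frame(records)
    labels = set(df["label"])
    for cls in (ACTIVE, DECOY):
        if cls not in labels:
            raise InvalidInputError(f"input contains no {cls} records")
    if direction not in (LOWER, HIGHER):
        raise InvalidInputError(f"direction must be '{LOWER}' or '{HIGHER}'")
    scores = df[score_field].astype(float)
    if scores.isna().any():
        raise InvalidInputError(f"missing values in {score_field}")
    ascending = direction == LOWER
    # stable sort: ties keep the input (compound_id table) order
    return df.sort_values(score_field, ascending=ascending, kind="stable")


def rank_and_curve(records, score_field: str = "modbind_score",
                   direction: str = LOWER) -> EnrichmentCurve:
    """Rank by score and accumulate the actives-found curve with its area."""
    ranked = _ranked(records, score_field, direction)
    is_active = (ranked["label"] == ACTIVE).to_numpy()
    n, A = len(ranked), int(is_active.sum())
    frac_screened = np.concatenate([[0.0], np.arange(1, n + 1) / n])
    frac_found = np.concatenate([[0.0], np.cumsum(is_active) / A])
    auc = float(np.trapezoid(frac_found, frac_screened))
    n_ties = int(n - ranked[score_field].nunique())
    return EnrichmentCurve(frac_screened, frac_found, auc, n_ties)


def ef_at_fraction(records, score_field: str = "modbind_score",
                   direction: str = LOWER, fraction: float = 0.05) -> float:
    """Enrichment factor in the top ``fraction`` of the ranked list (n >= 1)."""
    if not 0 < fraction <= 1:
        raise InvalidInputError(f"fraction must be in (0, 1], got {fraction}")
    ranked = _ranked(records, score_field, direction)
    N = len(ranked)
    A = int((ranked["label"] == ACTIVE).sum())
    n = max(1, int(np.floor(fraction * N)))
    a = int((ranked["label"].iloc[:n] == ACTIVE).sum())
    return enrichment_factor(EnrichmentInput(a=a, n=n, A=A, N=N))


def roc_auc(records, score_field: str = "modbind_score",
            direction: str = LOWER) -> float:
    """ROC area (Mann-Whitney; ties credited 1/2) for actives versus decoys."""
    df = _ranked(records, score_field, direction)  # validates classes/direction
    y = (df["label"] == ACTIVE).astype(int).to_numpy()
    s = df[score_field].astype(float).to_numpy()
    if direction == LOWER:
        s = -s
    return float(roc_auc_score(y, s))


def hit_rate_by_bin(records: pd.DataFrame, score_field: str,
                    bin_edges, hit_field: str = "hit") -> pd.DataFrame:
    """Per-bin compound counts and hit fractions (empty bins get n=0, rate NaN).

    ``bin_edges`` must be strictly increasing and cover the score range;
    bins are left-inclusive except the last, which includes both edges.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise InvalidInputError("bin edges must be strictly increasing (>= 2 edges)")
    scores = records[score_field].astype(float)
    if scores.min() < edges[0] or scores.max() > edges[-1]:
        raise InvalidInputError(
            f"bin edges [{edges[0]}, {edges[-1]}] do not cover the score range "
            f"[{scores.min()}, {scores.max()}]"
        )
    binned = pd.cut(scores, edges, include_lowest=True)
    hits = records[hit_field].astype(bool)
    grouped = hits.groupby(binned, observed=False)
    sizes = grouped.size()
    n_hits = grouped.sum()
    return pd.DataFrame(
        {
            "bin": [str(b) for b in sizes.index],
            "n": sizes.to_numpy(dtype=int),
            "hits": n_hits.reindex(sizes.index).fillna(0).to_numpy(dtype=int),
            "hit_rate": [
                h / n if n else np.nan
                for h, n in zip(n_hits.reindex(sizes.index).fillna(0), sizes)
            ],
        }
    )


def records_from_csv(path) -> pd.DataFrame:
    """Read a screening table (compound_id, label, docking_score, modbind_score)."""
    df = pd.read_csv(path)
    required = {"compound_id", "label"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"screen CSV missing columns: {sorted(missing)}")
    bad = set(df["label"]) - {ACTIVE, DECOY}
    if bad:
        raise InvalidInputError(f"unknown labels in screen CSV: {sorted(bad)}")
    return df
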