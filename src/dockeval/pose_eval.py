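"""Docking-outcome classification and pair-weighted success statistics.

A docking run is a table of records, one per (protein, ligand, receptor)
docking attempt.  A predicted pose is *correct* if its RMSD from the
experimental pose is <= 2.0 A (inclusive).  Aggregate accuracy weights
records so that each ligand-protein pair counts equally: within each
(protein, ligand, receptor_kind) group of M records every record gets weight
1/M, making the weighted accuracy identical to the unweighted mean of
per-pair success fractions.

Uncertainty is quantified with a pair-level percentile bootstrap (a pair's
full record set is resampled as a block), and two receptor kinds are
compared with a two-sided paired t-test on per-pair success fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .errors import InsufficientDataError

__all__ = [
    "POSE_RMSD_THRESHOLD",
    "MANIFEST_COLUMNS",
    "AccuracySummary",
    "PartitionResult",
    "classify_pose",
    "partition_records",
    "assign_weights",
    "weighted_accuracy",
    "bootstrap_ci",
    "paired_accuracy_test",
]

#: Pose-correctness criterion in Angstrom (inclusive).
POSE_RMSD_THRESHOLD = 2.0

#: Columns a run manifest must provide.
MANIFEST_COLUMNS = (
    "protein_id", "ligand_id", "receptor_id", "receptor_kind",
    "pose_rmsd", "is_self_dock", "receptor_ligand_similarity",
)

_PAIR = ["protein_id", "ligand_id"]
_GROUP = ["protein_id", "ligand_id", "receptor_kind"]


@dataclass(frozen=True)
class AccuracySummary:
    """Pair-weighted success fraction for one receptor kind, with 90% CI."""

    receptor_kind: str
    fraction_correct: float
    ci90: tuple
    n_pairs: int
    n_records: int

    def __post_init__(self) -> None:
        lo, hi = self.ci90
        if not (lo - 1e-12 <= self.fraction_correct <= hi + 1e-12):
            raise ValueError("point estimate must lie inside its CI")


@dataclass
class PartitionResult:
    """Filtered records plus a disjoint accounting of exclusions."""

    records: pd.DataFrame
    n_self_excluded: int
    n_similar_excluded: int

    @property
    def n_records(self) -> int:
        return len(self.records)


def classify_pose(rmsd: float, threshold: float = POSE_RMSD_THRESHOLD) -> bool:
    """True iff the pose RMSD is within the correctness criterion (inclusive)."""
    if rmsd < 0:
        raise ValueError(f"pose RMSD must be non-negative, got {rmsd}")
    return bool(rmsd <= threshold)


def _require_columns(records: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise KeyError(f"manifest is missing columns {missing}")


def _with_correct(records: pd.DataFrame, threshold: float = POSE_RMSD_THRESHOLD) -> pd.DataFrame:
    if "correct" in records.columns:
        return records
    if (records["pose_rmsd"] < 0).any():
        raise ValueError("pose RMSD must be non-negative")
    out = records.copy()
    out["correct"] = records["pose_rmsd"] <= threshold
    return out


def partition_records(
    records: pd.DataFrame,
    exclude_self_dock: bool = True,
    exclude_similar_receptor_ligand: bool = False,
    similarity_threshold: float = 0.5,
) -> PartitionResult:
    """Drop self-docking records and, optionally, experimental receptors whose
    bound ligand is similar (ratio >= threshold) to the docked ligand.

    Exclusions are disjointly accounted: self-docking is applied first, then
    the similarity filter on the remainder.
    """
    _require_columns(records, ["receptor_kind"])
    df = records
    n_self = 0
    if exclude_self_dock:
        _require_columns(df, ["is_self_dock"])
        mask = df["is_self_dock"].astype(bool)
        n_self = int(mask.sum())
        df = df.loc[~mask]
    n_similar = 0
    if exclude_similar_receptor_ligand:
        _require_columns(df, ["receptor_ligand_similarity"])
        experimental = df["receptor_kind"] == "experimental"
        sim = df["receptor_ligand_similarity"]
        if (experimental & sim.isna()).any():
            raise ValueError(
                "receptor_ligand_similarity missing for experimental receptors "
                "while the similarity filter is requested"
            )
        drop = experimental & (sim >= similarity_threshold)
        n_similar = int(drop.sum())
        df = df.loc[~drop]
    return PartitionResult(records=df.copy(), n_self_excluded=n_self,
                           n_similar_excluded=n_similar)


def assign_weights(records: pd.DataFrame) -> pd.DataFrame:
    """Weight = 1/M within each (protein, ligand, receptor_kind) group of size M."""
    _require_columns(records, _GROUP)
    out = records.copy()
    out["weight"] = 1.0 / out.groupby(_GROUP)["receptor_kind"].transform("size")
    return out


def weighted_accuracy(records: pd.DataFrame, threshold: float = POSE_RMSD_THRESHOLD) -> float:
    """Pair-equal weighted success fraction: sum(w * correct) / sum(w)."""
    if len(records) == 0:
        raise InsufficientDataError("cannot compute accuracy of zero records")
    df = _with_correct(records, threshold)
    if "weight" not in df.columns:
        df = assign_weights(df)
    w = df["weight"].to_numpy(dtype=float)
    y = df["correct"].to_numpy(dtype=float)
    return float(np.sum(w * y) / np.sum(w))


def _pair_aggregates(records: pd.DataFrame, threshold: float):
    """Per-pair (sum of weights, sum of weighted successes)."""
    df = _with_correct(records, threshold)
    if "weight" not in df.columns:
        df = assign_weights(df)
    df = df.assign(_wy=df["weight"] * df["correct"].astype(float))
    agg = df.groupby(_PAIR, sort=True).agg(w=("weight", "sum"), wy=("_wy", "sum"))
    return agg["w"].to_numpy(), agg["wy"].to_numpy()


def bootstrap_ci(
    records: pd.DataFrame,
    level: float = 0.90,
    n_resamples: int = 9999,
    seed: int = 0,
    threshold: float = POSE_RMSD_THRESHOLD,
) -> tuple:
    """Percentile bootstrap CI for the pair-weighted accuracy.

    The resampling unit is the ligand-protein pair: a pair's full record set
    moves together, so within-pair correlation is respected.  Reproducible
    for a fixed seed.
    """
    w, wy = _pair_aggregates(records, threshold)
    n_pairs = len(w)
    if n_pairs < 2:
        warnings.warn("single ligand-protein pair: degenerate CI equals the point estimate",
                      stacklevel=2)
        point = float(wy.sum() / w.sum())
        return (point, point)
    rng = substream(seed, "bootstrap-ci")
    idx = rng.integers(0, n_pairs, size=(n_resamples, n_pairs))
    stat = wy[idx].sum(axis=1) / w[idx].sum(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stat, [alpha, 1.0 - alpha])
    return (float(lo), float(hi))


def per_pair_fractions(records: pd.DataFrame, threshold: float = POSE_RMSD_THRESHOLD) -> pd.Series:
    """Per ligand-protein pair, the weighted success fraction of its records."""
    w, wy = _pair_aggregates(records, threshold)
    df = _with_correct(records, threshold)
    if "weight" not in df.columns:
        df = assign_weights(df)
    keys = df.groupby(_PAIR, sort=True).size().index
    return pd.Series(wy / w, index=keys, name="fraction_correct")


def paired_accuracy_test(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    threshold: float = POSE_RMSD_THRESHOLD,
) -> float:
    """Two-sided paired t-test on per-pair success fractions of two kinds.

    Pairs present in only one input are dropped (and counted in a warning).
    All-zero differences (identical per-pair fractions) give p = 1 by
    convention; zero-variance non-zero differences give p = 0.
    """
    fa = per_pair_fractions(records_a, threshold)
    fb = per_pair_fractions(records_b, threshold)
    common = fa.index.intersection(fb.index)
    dropped = (len(fa) - len(common)) + (len(fb) - len(common))
    if dropped:
        warnings.warn(f"{dropped} pair entries present in only one kind were dropped",
                      stacklevel=2)
    if len(common) < 2:
        raise InsufficientDataError(
            f"paired test needs >= 2 common ligand-protein pairs, got {len(common)}"
        )
    diffs = (fa.loc[common] - fb.loc[common]).to_numpy(dtype=float)
    if np.allclose(diffs, 0.0):
        warnings.warn("all per-pair differences are zero; p = 1 by convention", stacklevel=2)
        return 1.0
    if np.isclose(diffs.std(ddof=1), 0.0):
        warnings.warn("zero-variance non-zero differences; p = 0", stacklevel=2)
        return 0.0
    result = stats.ttest_rel(fa.loc[common], fb.loc[common], alternative="two-sided")
    return float(result.pvalue)


def summarize_accuracy(
    records: pd.DataFrame,
    level: float = 0.90,
    n_resamples: int = 9999,
    seed: int = 0,
    threshold: float = POSE_RMSD_THRESHOLD,
) -> dict:
    """Per receptor kind, the pair-weighted accuracy with a bootstrap CI."""
    _require_columns(records, ["receptor_kind"])
    out = {}
    for kind, group in records.groupby("receptor_kind", sort=True):
        frac = weighted_accuracy(group, threshold)
        ci = bootstrap_ci(group, level=level, n_resamples=n_resamples,
                          seed=seed, threshold=threshold)
        # the point estimate can fall marginally outside a percentile CI only
        # in degenerate tiny samples; clip for the invariant
        ci = (min(ci[0], frac), max(ci[1], frac))
        n_pairs = group.groupby(_PAIR).ngroups
        out[kind] = AccuracySummary(
            receptor_kind=str(kind), fraction_correct=frac, ci90=ci,
            n_pairs=int(n_pairs), n_records=int(len(group)),
        )
    return out
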