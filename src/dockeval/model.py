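"""Model/Results interface over a docking-run manifest.

``DockingAccuracyModel`` wraps a run manifest (one row per protein x ligand x
receptor docking attempt) and owns the evaluation design choices: the pose
correctness threshold, which records are excluded (self-docking, similar
receptor ligands), and the pair-equal weighting.  ``fit`` produces a
``DockingAccuracyResults`` carrying per-receptor-kind accuracies with
bootstrap confidence intervals, pairwise paired-t comparisons, and access to
kernel-smoothed accuracy-versus-pocket-RMSD curves.

Example
-------
>>> model = DockingAccuracyModel.from_manifest("runs.csv")
>>> res = model.fit(seed=17)
>>> print(res.summary())
>>> curve = res.smooth("af2", band=True, seed=17)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import pose_eval, smoothing
from .errors import InsufficientDataError

__all__ = ["DockingAccuracyModel", "DockingAccuracyResults"]


class DockingAccuracyModel:
    """Pair-weighted docking-success model built from a run manifest.

    Parameters
    ----------
    records
        DataFrame with at least ``protein_id, ligand_id, receptor_id,
        receptor_kind, pose_rmsd``; ``is_self_dock`` and
        ``receptor_ligand_similarity`` are required by the corresponding
        exclusion filters, and ``pocket_rmsd`` by the smoothed curves.
    threshold
        Pose-correctness criterion in Angstrom (inclusive; default 2.0).
    exclude_self_dock, exclude_similar_receptor_ligand, similarity_threshold
        Record filters applied before any statistic is computed.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        threshold: float = pose_eval.POSE_RMSD_THRESHOLD,
        exclude_self_dock: bool = True,
        exclude_similar_receptor_ligand: bool = False,
        similarity_threshold: float = 0.5,
    ) -> None:
        if len(records) == 0:
            raise InsufficientDataError("empty manifest")
        self.raw_records = records.copy()
        self.threshold = float(threshold)
        part = pose_eval.partition_records(
            records,
            exclude_self_dock=exclude_self_dock,
            exclude_similar_receptor_ligand=exclude_similar_receptor_ligand,
            similarity_threshold=similarity_threshold,
        )
        self.partition = part
        df = pose_eval.assign_weights(part.records)
        if (df["pose_rmsd"] < 0).any():
            raise ValueError("pose RMSD must be non-negative")
        df["correct"] = df["pose_rmsd"] <= self.threshold
        self.records = df

    @classmethod
    def from_manifest(cls, path, **kwargs) -> "DockingAccuracyModel":
        """Build from a manifest CSV (columns as in ``MANIFEST_COLUMNS``)."""
        return cls(pd.read_csv(path), **kwargs)

    @property
    def kinds(self) -> list:
        return sorted(self.records["receptor_kind"].unique())

    def fit(
        self,
        level: float = 0.90,
        n_resamples: int = 9999,
        seed: int = 0,
    ) -> "DockingAccuracyResults":
        """Estimate per-kind accuracies, bootstrap CIs and pairwise tests."""
        summaries = pose_eval.summarize_accuracy(
            self.records, level=level, n_resamples=n_resamples,
            seed=seed, threshold=self.threshold,
        )
        pvals = {}
        kinds = self.kinds
        for i, ka in enumerate(kinds):
            for kb in kinds[i + 1:]:
                a = self.records[self.records["receptor_kind"] == ka]
                b = self.records[self.records["receptor_kind"] == kb]
                try:
                    pvals[(ka, kb)] = pose_eval.paired_accuracy_test(a, b, self.threshold)
                except InsufficientDataError:
                    pvals[(ka, kb)] = np.nan
        return DockingAccuracyResults(
            model=self, accuracy=summaries, pairwise_pvalues=pvals,
            level=level, n_resamples=n_resamples, seed=seed,
        )


@dataclass
class DockingAccuracyResults:
    """Fitted docking-accuracy estimates and their uncertainties."""

    model: DockingAccuracyModel
    accuracy: dict
    pairwise_pvalues: dict
    level: float
    n_resamples: int
    seed: int = 0
    _curves: dict = field(default_factory=dict, repr=False)

    def accuracy_frame(self) -> pd.DataFrame:
        rows = []
        for kind, s in self.accuracy.items():
            rows.append({
                "receptor_kind": kind,
                "fraction_correct": s.fraction_correct,
                "ci_lo": s.ci90[0],
                "ci_hi": s.ci90[1],
                "n_pairs": s.n_pairs,
                "n_records": s.n_records,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable table of accuracies, CIs and pairwise p-values."""
        part = self.model.partition
        lines = [
            "Docking pose-prediction accuracy (pair-equal weighting)",
            f"  correctness criterion: pose RMSD <= {self.model.threshold:.1f} A",
            f"  records used: {len(self.model.records)}"
            f"  (excluded: {part.n_self_excluded} self-dock,"
            f" {part.n_similar_excluded} similar-ligand)",
            f"  bootstrap: {int(self.level * 100)}% percentile CI,"
            f" {self.n_resamples} resamples, pair-level blocks",
            "",
            f"  {'receptor kind':<14}{'accuracy':>9}{'ci lo':>8}{'ci hi':>8}"
            f"{'pairs':>7}{'records':>9}",
        ]
        for kind, s in sorted(self.accuracy.items()):
            lines.append(
                f"  {kind:<14}{s.fraction_correct:9.3f}{s.ci90[0]:8.3f}"
                f"{s.ci90[1]:8.3f}{s.n_pairs:7d}{s.n_records:9d}"
            )
        if self.pairwise_pvalues:
            lines.append("")
            lines.append("  paired t-tests on per-pair success fractions:")
            for (ka, kb), p in sorted(self.pairwise_pvalues.items()):
                shown = "nan" if p != p else f"{p:.4g}"
                lines.append(f"    {ka} vs {kb}: p = {shown}")
        return "\n".join(lines)

    # -- smoothed curves ----------------------------------------------------

    def _kind_records(self, kind: str) -> pd.DataFrame:
        df = self.model.records
        out = df[df["receptor_kind"] == kind]
        if len(out) == 0:
            raise InsufficientDataError(f"no records of kind {kind!r}")
        if "pocket_rmsd" not in out.columns or out["pocket_rmsd"].isna().all():
            raise InsufficientDataError("manifest has no pocket_rmsd column to smooth over")
        return out

    def smooth(
        self,
        kind: str,
        bandwidth: float = smoothing.DEFAULT_BANDWIDTH,
        band: bool = False,
        n_resamples: int = 9999,
        seed: Optional[int] = None,
        weighted: bool = True,
        grid_step: float = smoothing.DEFAULT_GRID_STEP,
    ) -> smoothing.SmoothedCurve:
        """Kernel-smoothed success vs pocket RMSD for one receptor kind."""
        df = self._kind_records(kind)
        weights = df["weight"].to_numpy() if weighted else None
        if band:
            return smoothing.bootstrap_band(
                df, weights=weights, bandwidth=bandwidth, level=self.level,
                n_resamples=n_resamples, grid_step=grid_step,
                seed=self.seed if seed is None else seed,
            )
        return smoothing.smooth_accuracy(df, weights=weights, bandwidth=bandwidth,
                                         grid_step=grid_step)

    def compare_curves(
        self,
        kind_a: str,
        kind_b: str,
        bandwidth: float = smoothing.DEFAULT_BANDWIDTH,
        n_resamples: int = 9999,
        seed: Optional[int] = None,
        weighted: bool = True,
        grid_step: float = smoothing.DEFAULT_GRID_STEP,
    ) -> smoothing.CurveComparison:
        """Per-grid-point bootstrap significance of curve A minus curve B."""
        a = self._kind_records(kind_a)
        b = self._kind_records(kind_b)
        return smoothing.curve_difference_test(
            a, b,
            weights_a=a["weight"].to_numpy() if weighted else None,
            weights_b=b["weight"].to_numpy() if weighted else None,
            bandwidth=bandwidth, grid_step=grid_step, n_resamples=n_resamples,
            seed=self.seed if seed is None else seed,
        )

    def plot(self, kinds: Optional[list] = None, ax=None, band: bool = False,
             n_resamples: int = 999, **kwargs):
        """Plot smoothed accuracy curves (matplotlib imported lazily)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for kind in kinds or self.model.kinds:
            curve = self.smooth(kind, band=band, n_resamples=n_resamples, **kwargs)
            (line,) = ax.plot(curve.grid, curve.estimate, label=kind)
            if band and curve.band_lo is not None:
                ax.fill_between(curve.grid, curve.band_lo, curve.band_hi,
                                alpha=0.2, color=line.get_color())
        ax.set_xlabel("binding pocket RMSD (A)")
        ax.set_ylabel("fraction of poses correct")
        ax.set_ylim(-0.02, 1.02)
        ax.legend()
        return ax
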