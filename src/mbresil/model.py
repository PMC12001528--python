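"""Model/Results surface tying the whole resilience analysis together.

:class:`MicrobiomeResilience` is constructed from an abundance table plus
sample metadata and holds the analysis options; :meth:`fit` executes the
pipeline

    zero replacement -> log-ratio taxon selection -> distance trajectories
    -> functional PCA -> score/distance correlations -> bagplot outliers

and returns a :class:`ResilienceResults` carrying every intermediate artifact
(selected taxa with contributions, the trajectory family, the fitted FPCA
model, per-trajectory scores with outlier flags, group summaries) together
with a text ``summary()``.  Score-grid simulation hangs off the results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import fpca as _fpca
from . import lra as _lra
from . import outliers as _outliers
from . import trajectories as _traj
from .compositions import AbundanceTable, ZeroReplacementParams, replace_zeros

__all__ = ["MicrobiomeResilience", "ResilienceResults"]


class MicrobiomeResilience:
    """Bivariate resilience analysis of a longitudinal abundance study.

    Parameters
    ----------
    table:
        Samples × taxa counts or relative abundances.
    metadata:
        Per-sample subject, condition, timepoint and baseline flag.
    zero_replacement:
        How zeros are imputed before any log-ratio operation.
    lra_threshold:
        Keep the minimum set of taxa explaining at least this fraction of
        the total log-ratio variance (set to 1.0 to keep all taxa).
    baseline_mode, fixed_baseline, baseline_condition, include_t0:
        Baseline resolution for the distance trajectories.
    K, fpca_weights:
        Number of functional components and the quadrature scheme.
    bagplot_min_n, fence_factor:
        Outlier detection; skipped (flags missing) below ``bagplot_min_n``
        trajectories.
    """

    def __init__(
        self,
        table: AbundanceTable,
        metadata: pd.DataFrame,
        *,
        zero_replacement: ZeroReplacementParams | None = None,
        lra_threshold: float = 0.9,
        baseline_mode: Literal["per_condition", "per_subject", "fixed_sample"] = "per_condition",
        fixed_baseline: str | None = None,
        baseline_condition: str | None = None,
        include_t0: bool = True,
        missing: Literal["drop", "interpolate"] = "drop",
        K: int = 2,
        fpca_weights: Literal["trapezoid", "uniform"] = "trapezoid",
        bagplot_min_n: int = 10,
        fence_factor: float = 3.0,
    ):
        self.table = table
        self.metadata = _traj.validate_metadata(metadata)
        self.zero_replacement = zero_replacement or ZeroReplacementParams()
        if not (0 < lra_threshold <= 1):
            raise ValueError("lra_threshold must be in (0, 1]")
        self.lra_threshold = lra_threshold
        self.baseline_mode = baseline_mode
        self.fixed_baseline = fixed_baseline
        self.baseline_condition = baseline_condition
        self.include_t0 = include_t0
        self.missing = missing
        if K < 1:
            raise ValueError("K must be >= 1")
        self.K = K
        self.fpca_weights = fpca_weights
        self.bagplot_min_n = bagplot_min_n
        self.fence_factor = fence_factor

    @classmethod
    def from_dataframes(
        cls, abundances: pd.DataFrame, metadata: pd.DataFrame, **options
    ) -> "MicrobiomeResilience":
        """Build from a raw samples × taxa DataFrame (index = sample ids)."""
        return cls(AbundanceTable(abundances), metadata, **options)

    def fit(self) -> "ResilienceResults":
        """Run the full analysis and collect every artifact."""
        positive = replace_zeros(self.table, self.zero_replacement)
        lra_result = _lra.lra_fit(positive)
        selected = _lra.select_taxa(lra_result, self.lra_threshold)
        reduced = _lra.subset_and_reclose(positive, selected)
        ts = _traj.build_trajectories(
            reduced,
            self.metadata,
            baseline_mode=self.baseline_mode,
            fixed_baseline=self.fixed_baseline,
            baseline_condition=self.baseline_condition,
            include_t0=self.include_t0,
            missing=self.missing,
        )
        K = min(self.K, len(ts) - 1, len(ts.grid))
        model = _fpca.fpca_fit(ts, K=K, weights=self.fpca_weights)
        scores = _fpca.fpca_scores(model, ts)
        correlations = (
            _fpca.score_distance_correlation(scores, ts) if len(ts) >= 3 else None
        )
        if model.K >= 2 and len(scores) >= self.bagplot_min_n:
            scores = _outliers.flag_outlier_trajectories(
                scores, fence_factor=self.fence_factor, min_n=self.bagplot_min_n
            )
        group_summary = _fpca.score_group_summary(scores, by="condition")
        mean_dist, se_dist = _traj.overall_mean_distance(ts)
        return ResilienceResults(
            model=self,
            positive_table=positive,
            lra=lra_result,
            selected_taxa=selected,
            reduced_table=reduced,
            trajectories=ts,
            fpca=model,
            scores=scores,
            correlations=correlations,
            group_summary=group_summary,
            mean_distance=mean_dist,
            se_distance=se_dist,
        )


@dataclass
class ResilienceResults:
    """Artifacts of a fitted resilience analysis."""

    model: MicrobiomeResilience
    positive_table: AbundanceTable       # zero-replaced, closed
    lra: _lra.LRAResult
    selected_taxa: list[str]
    reduced_table: AbundanceTable        # selected taxa, re-closed
    trajectories: _traj.TrajectorySet
    fpca: _fpca.FPCAModel
    scores: pd.DataFrame                 # FPCA1..K (+ depth/outlier when fitted)
    correlations: pd.DataFrame | None    # score × time Pearson r
    group_summary: pd.DataFrame          # per-condition mean ± sd of scores
    mean_distance: float                 # pooled non-baseline mean distance
    se_distance: float

    # -- convenience -----------------------------------------------------
    @property
    def explained_fractions(self) -> np.ndarray:
        return self.fpca.explained_fractions

    def ranked_taxa(self) -> pd.DataFrame:
        """Selected taxa with their variance contributions, ranked."""
        ranked = self.lra.ranked()
        return ranked[ranked["taxon_id"].isin(self.selected_taxa)].reset_index(drop=True)

    def group_mean_curves(self, by: str = "condition") -> pd.DataFrame:
        """Mean ± SE distance at each time, per condition (or subject)."""
        return _traj.group_mean_se(self.trajectories, by=by)

    def simulate(
        self, xi1_values: Sequence[float], xi2_values: Sequence[float]
    ) -> _traj.TrajectorySet:
        """Curves on a Cartesian grid of the first two scores."""
        return _fpca.simulate_family(self.fpca, xi1_values, xi2_values)

    def outlier_labels(self) -> list[tuple[str, str]]:
        if "outlier" not in self.scores.columns:
            return []
        flagged = self.scores.loc[self.scores["outlier"], ["subject_id", "condition"]]
        return list(flagged.itertuples(index=False, name=None))

    def summary(self) -> str:
        """Human-readable recap of the fitted analysis."""
        width = 62
        lines = []
        lines.append("Microbiome resilience analysis".center(width))
        lines.append("=" * width)
        lines.append(
            f"Trajectories: {len(self.trajectories):>4}    "
            f"Conditions: {self.scores['condition'].nunique():>2}    "
            f"Grid (h): {', '.join(f'{t:g}' for t in self.trajectories.grid)}"
        )
        lines.append(
            f"Taxa: {self.model.table.n_taxa} input -> {len(self.selected_taxa)} selected "
            f"(>= {self.model.lra_threshold:.0%} of log-ratio variance)"
        )
        lines.append(
            f"Mean distance from baseline: {self.mean_distance:.3g} "
            f"+/- {self.se_distance:.2g} (SE)"
        )
        lines.append("-" * width)
        for k in range(self.fpca.K):
            lines.append(
                f"FPCA{k + 1}: eigenvalue {self.fpca.eigenvalues[k]:.4g}, "
                f"explains {self.explained_fractions[k]:.1%} of trajectory variance"
            )
        lines.append("-" * width)
        lines.append("Score means +/- sd by condition:")
        for _, row in self.group_summary.iterrows():
            sd = f"{row['sd']:.2f}" if np.isfinite(row["sd"]) else "n/a"
            lines.append(
                f"  {row['condition']:<12} {row['score']:<6} "
                f"{row['mean']:>8.2f} +/- {sd} (n={int(row['n'])})"
            )
        outliers = self.outlier_labels()
        if "outlier" in self.scores.columns:
            label = (
                ", ".join(f"{s}/{c}" for s, c in outliers) if outliers else "none"
            )
            lines.append(f"Bagplot outlier trajectories: {label}")
        lines.append("=" * width)
        return "\n".join(lines)
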