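"""Distance trajectories: per-(subject, condition) microbiome change curves.

A *trajectory* summarises how far a subject's microbial community has moved
from a reference (baseline) composition: for each post-baseline sample the
Aitchison distance to the baseline sample is computed, yielding a time-indexed
curve.  Families of such curves are the input to functional PCA.

Baselines can be resolved three ways:

``per_condition``
    the flagged baseline sample of each (subject, condition) — the usual
    pre-perturbation sample collected just before each challenge;
``per_subject``
    one baseline per subject, shared across conditions (optionally pinned to
    a named condition), useful to measure long-term drift of the
    pre-perturbation state itself;
``fixed_sample``
    one explicit sample used as the reference for every trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .compositions import AbundanceTable, CompositionError, clr

__all__ = [
    "REQUIRED_METADATA_COLUMNS",
    "TrajectoryError",
    "validate_metadata",
    "Trajectory",
    "TrajectorySet",
    "build_trajectories",
    "group_mean_se",
    "overall_mean_distance",
]

REQUIRED_METADATA_COLUMNS = ("sample_id", "subject_id", "condition", "time_h", "is_baseline")

_TRUTHY = {"true", "1", "yes", "t"}
_FALSY = {"false", "0", "no", "f"}


class TrajectoryError(ValueError):
    """Metadata or baseline resolution failed."""


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a sample-metadata table.

    Requires the columns ``sample_id, subject_id, condition, time_h,
    is_baseline``; coerces ``time_h`` to float and ``is_baseline`` to bool
    (accepting true/false, 1/0, yes/no case-insensitively).  Rejects duplicate
    sample ids, duplicate (subject, condition, time) triples, and negative or
    non-finite times.
    """
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise TrajectoryError(f"metadata missing required column(s): {missing}")
    out = meta.loc[:, list(REQUIRED_METADATA_COLUMNS)].copy()
    for col in ("sample_id", "subject_id", "condition"):
        out[col] = out[col].astype(str)
    try:
        out["time_h"] = out["time_h"].astype(float)
    except (TypeError, ValueError) as exc:
        raise TrajectoryError(f"unparseable time_h values: {exc}") from None
    if not np.all(np.isfinite(out["time_h"])) or (out["time_h"] < 0).any():
        bad = out.loc[~np.isfinite(out["time_h"]) | (out["time_h"] < 0), "sample_id"].tolist()
        raise TrajectoryError(f"negative or non-finite time_h for sample(s): {bad}")

    def _to_bool(v) -> bool:
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        s = str(v).strip().lower()
        if s in _TRUTHY:
            return True
        if s in _FALSY:
            return False
        raise TrajectoryError(f"unparseable is_baseline value: {v!r}")

    out["is_baseline"] = out["is_baseline"].map(_to_bool)
    dup = out["sample_id"][out["sample_id"].duplicated()].unique().tolist()
    if dup:
        raise TrajectoryError(f"duplicate sample id(s) in metadata: {dup}")
    key = out[["subject_id", "condition", "time_h"]]
    dupk = key[key.duplicated()].drop_duplicates().to_records(index=False).tolist()
    if dupk:
        raise TrajectoryError(f"duplicate (subject, condition, time_h): {dupk}")
    return out.reset_index(drop=True)


@dataclass
class Trajectory:
    """One subject × condition distance-from-baseline curve."""

    subject_id: str
    condition: str
    times: np.ndarray
    distances: np.ndarray
    #: time of the zero anchor contributed by the baseline sample itself,
    #: or None when the curve starts at the first post-baseline sample
    baseline_time: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.times.shape != self.distances.shape or self.times.ndim != 1:
            raise TrajectoryError("times and distances must be 1-D and equal length")
        if len(self.times) and not np.all(np.diff(self.times) > 0):
            raise TrajectoryError("times must be strictly increasing")
        # Observed distance curves are norms and hence non-negative; curves
        # synthesized from an FPCA model may dip below zero, so only
        # finiteness is enforced here.
        if not np.all(np.isfinite(self.distances)):
            raise TrajectoryError("distances must be finite")

    @property
    def label(self) -> tuple[str, str]:
        return (self.subject_id, self.condition)


@dataclass
class TrajectorySet:
    """A family of trajectories sharing (up to missingness) a common grid."""

    trajectories: list[Trajectory]
    grid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.grid is None:
            times = sorted({float(t) for tr in self.trajectories for t in tr.times})
            self.grid = np.asarray(times, dtype=float)
        else:
            self.grid = np.asarray(self.grid, dtype=float)

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def labels(self) -> list[tuple[str, str]]:
        return [tr.label for tr in self.trajectories]

    def curve_matrix(self) -> np.ndarray:
        """Stack trajectories into an ``n × m`` matrix on the common grid.

        Every trajectory must be observed at exactly the grid times; use the
        ``missing="interpolate"`` build policy first if they are not.
        """
        m = len(self.grid)
        rows = []
        for tr in self.trajectories:
            if len(tr.times) != m or not np.allclose(tr.times, self.grid):
                raise TrajectoryError(
                    f"trajectory {tr.label} is not observed on the common grid"
                )
            rows.append(tr.distances)
        return np.vstack(rows)

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: subject_id, condition, time_h, distance."""
        recs = [
            (tr.subject_id, tr.condition, t, d)
            for tr in self.trajectories
            for t, d in zip(tr.times, tr.distances)
        ]
        return pd.DataFrame(recs, columns=["subject_id", "condition", "time_h", "distance"])


def _resolve_baselines(
    meta: pd.DataFrame,
    baseline_mode: str,
    fixed_baseline: str | None,
    baseline_condition: str | None,
) -> dict[tuple[str, str], str]:
    """Map each (subject, condition) group to its baseline sample id."""
    groups = meta.groupby(["subject_id", "condition"], sort=True)
    baselines: dict[tuple[str, str], str] = {}
    if baseline_mode == "per_condition":
        for key, grp in groups:
            flagged = grp.loc[grp["is_baseline"], "sample_id"].tolist()
            if len(flagged) != 1:
                raise TrajectoryError(
                    f"expected exactly one baseline for (subject={key[0]}, "
                    f"condition={key[1]}), found {len(flagged)}"
                )
            baselines[key] = flagged[0]
    elif baseline_mode == "per_subject":
        for subject, grp in meta.groupby("subject_id", sort=True):
            cand = grp.loc[grp["is_baseline"]]
            if baseline_condition is not None:
                cand = cand.loc[cand["condition"] == baseline_condition]
            if len(cand) != 1:
                raise TrajectoryError(
                    f"expected exactly one baseline for subject {subject}"
                    + (f" in condition {baseline_condition!r}" if baseline_condition else "")
                    + f", found {len(cand)}"
                )
            sid = cand["sample_id"].iloc[0]
            for key in groups.groups:
                if key[0] == subject:
                    baselines[key] = sid
    elif baseline_mode == "fixed_sample":
        if fixed_baseline is None:
            raise TrajectoryError("fixed_sample mode requires fixed_baseline")
        if fixed_baseline not in set(meta["sample_id"]):
            raise TrajectoryError(f"fixed baseline sample {fixed_baseline!r} not in metadata")
        for key in groups.groups:
            baselines[key] = fixed_baseline
    else:
        raise TrajectoryError(f"unknown baseline_mode {baseline_mode!r}")
    return baselines


def build_trajectories(
    table: AbundanceTable,
    meta: pd.DataFrame,
    *,
    baseline_mode: Literal["per_condition", "per_subject", "fixed_sample"] = "per_condition",
    fixed_baseline: str | None = None,
    baseline_condition: str | None = None,
    include_t0: bool = True,
    missing: Literal["drop", "interpolate"] = "drop",
) -> TrajectorySet:
    """Compute Aitchison distance-from-baseline curves for every group.

    For each (subject, condition) group in ``meta`` the distance of every
    non-baseline sample to the group's baseline composition is computed; with
    ``include_t0`` the baseline contributes a zero anchor at its own time.
    The table must be strictly positive (zeros replaced).

    ``missing="interpolate"`` linearly interpolates each trajectory onto the
    common grid (endpoint values are held constant outside the observed span);
    ``"drop"`` keeps only observed times, in which case ragged families cannot
    be stacked for FPCA.
    """
    meta = validate_metadata(meta)
    if not table.is_strictly_positive():
        raise CompositionError("zeros present: run replace_zeros before building trajectories")
    absent = sorted(set(meta["sample_id"]) - set(table.sample_ids))
    if absent:
        raise TrajectoryError(f"metadata sample(s) absent from abundance table: {absent}")

    baselines = _resolve_baselines(meta, baseline_mode, fixed_baseline, baseline_condition)

    clr_all = pd.DataFrame(clr(table.values), index=table.sample_ids)
    trajectories: list[Trajectory] = []
    for key, grp in meta.groupby(["subject_id", "condition"], sort=True):
        base_id = baselines[key]
        base_clr = clr_all.loc[base_id].to_numpy()
        obs = grp.loc[grp["sample_id"] != base_id].sort_values("time_h")
        times = obs["time_h"].to_numpy(dtype=float)
        dists = np.linalg.norm(
            clr_all.loc[obs["sample_id"]].to_numpy() - base_clr, axis=1
        )
        baseline_time: float | None = None
        if include_t0 and base_id in set(grp["sample_id"]):
            t0 = float(grp.loc[grp["sample_id"] == base_id, "time_h"].iloc[0])
            if t0 in times:
                raise TrajectoryError(
                    f"baseline time {t0} collides with an observation in group {key}"
                )
            times = np.concatenate([[t0], times])
            dists = np.concatenate([[0.0], dists])
            order = np.argsort(times)
            times, dists = times[order], dists[order]
            baseline_time = t0
        trajectories.append(
            Trajectory(
                subject_id=key[0],
                condition=key[1],
                times=times,
                distances=dists,
                baseline_time=baseline_time,
            )
        )
    if not trajectories:
        raise TrajectoryError("no (subject, condition) groups in metadata")

    ts = TrajectorySet(trajectories)
    if missing == "interpolate":
        interp = [
            Trajectory(
                tr.subject_id,
                tr.condition,
                ts.grid,
                np.interp(ts.grid, tr.times, tr.distances),
                baseline_time=tr.baseline_time,
            )
            for tr in ts
        ]
        ts = TrajectorySet(interp, grid=ts.grid)
    elif missing != "drop":
        raise TrajectoryError(f"unknown missing policy {missing!r}")
    return ts


def _mean_se(values: np.ndarray) -> tuple[float, float, int]:
    n = len(values)
    mean = float(np.mean(values))
    se = float(np.std(values, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return mean, se, n


def group_mean_se(ts: TrajectorySet, by: str = "condition") -> pd.DataFrame:
    """Mean ± standard error of the distance at each grid time, per group.

    ``by`` is a trajectory attribute, ``"condition"`` or ``"subject_id"``.
    The SE uses the n−1 sample standard deviation and is reported as missing
    (NaN) when only one trajectory contributes.
    """
    if len(ts) == 0:
        raise TrajectoryError("empty trajectory set")
    if by not in ("condition", "subject_id"):
        raise TrajectoryError(f"unsupported grouping key {by!r}")
    long = ts.to_frame()
    records = []
    for (grp, t), sub in long.groupby([by, "time_h"], sort=True):
        mean, se, n = _mean_se(sub["distance"].to_numpy())
        records.append((grp, t, mean, se, n))
    return pd.DataFrame(records, columns=[by, "time_h", "mean", "se", "n"])


def overall_mean_distance(ts: TrajectorySet) -> tuple[float, float]:
    """Pooled mean ± SE of every non-baseline distance observation.

    Zero anchors contributed by the baseline samples themselves are excluded
    so the statistic reflects actual displacement from the reference.
    """
    pool: list[float] = []
    for tr in ts:
        mask = np.ones(len(tr.times), dtype=bool)
        if tr.baseline_time is not None:
            mask &= tr.times != tr.baseline_time
        pool.extend(tr.distances[mask])
    if not pool:
        raise TrajectoryError("no non-baseline observations to pool")
    mean, se, _ = _mean_se(np.asarray(pool))
    return mean, se
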