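"""Readers and writers for the plain-text formats used across the toolkit.

Abundance tables and metadata are TSV/CSV (dialect inferred from the file
extension, tab for ``.tsv``/``.txt`` and comma otherwise); trajectories and
scores are long-format CSV; fitted FPCA models are JSON.  Floating-point
output uses nine significant digits so written artifacts are byte-stable and
round-trip through the package's own readers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .compositions import AbundanceTable, CompositionError
from .fpca import FPCAModel
from .trajectories import (
    REQUIRED_METADATA_COLUMNS,
    Trajectory,
    TrajectorySet,
    TrajectoryError,
    validate_metadata,
)

__all__ = [
    "FLOAT_FORMAT",
    "read_abundance_table",
    "write_abundance_table",
    "read_metadata",
    "write_metadata",
    "read_trajectories",
    "write_trajectories",
    "read_scores",
    "write_scores",
    "read_fpca_model",
    "write_fpca_model",
]

FLOAT_FORMAT = "%.9g"


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".txt")) else ","


def read_abundance_table(path: str | Path) -> AbundanceTable:
    """Read a samples × taxa table (first column = sample id, header required)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.shape[1] == 0:
        raise CompositionError(f"{path}: no taxon columns found")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise CompositionError(f"{path}: non-numeric abundance values ({exc})") from None
    return AbundanceTable(df)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    table.data.rename_axis("sample_id").to_csv(
        path, sep=_sep_for(path), float_format=FLOAT_FORMAT
    )


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample-metadata table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    return validate_metadata(df)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    validate_metadata(meta).to_csv(path, sep=_sep_for(path), index=False)


def write_trajectories(ts: TrajectorySet, path: str | Path) -> None:
    """Write a trajectory family as long-format CSV.

    Columns: subject_id, condition, time_h, distance, is_baseline_anchor.
    The long format tolerates trajectories observed on different time sets.
    """
    frame = ts.to_frame()
    anchors = {
        tr.label: tr.baseline_time for tr in ts if tr.baseline_time is not None
    }
    frame["is_baseline_anchor"] = [
        anchors.get((s, c)) == t
        for s, c, t in zip(frame["subject_id"], frame["condition"], frame["time_h"])
    ]
    frame.to_csv(path, sep=_sep_for(path), index=False, float_format=FLOAT_FORMAT)


def read_trajectories(path: str | Path) -> TrajectorySet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"subject_id", "condition", "time_h", "distance"}
    missing = required - set(df.columns)
    if missing:
        raise TrajectoryError(f"{path}: missing column(s) {sorted(missing)}")
    has_anchor = "is_baseline_anchor" in df.columns
    trajectories = []
    for (subject, condition), grp in df.groupby(
        ["subject_id", "condition"], sort=True
    ):
        grp = grp.sort_values("time_h")
        baseline_time = None
        if has_anchor and grp["is_baseline_anchor"].any():
            baseline_time = float(grp.loc[grp["is_baseline_anchor"], "time_h"].iloc[0])
        trajectories.append(
            Trajectory(
                str(subject),
                str(condition),
                grp["time_h"].to_numpy(dtype=float),
                grp["distance"].to_numpy(dtype=float),
                baseline_time=baseline_time,
            )
        )
    return TrajectorySet(trajectories)


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep=_sep_for(path), index=False, float_format=FLOAT_FORMAT)


def read_scores(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if "subject_id" not in df.columns or "FPCA1" not in df.columns:
        raise ValueError(f"{path}: not a score table (needs subject_id and FPCA1)")
    return df


def write_fpca_model(model: FPCAModel, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_fpca_model(path: str | Path) -> FPCAModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        return FPCAModel.from_dict(json.load(fh))
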