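"""Functional PCA of distance-trajectory families.

Each trajectory is treated as a discretised curve X_i(t) on a shared time
grid.  The Karhunen–Loève expansion

    X_i(t) = mu(t) + sum_k xi_ik * phi_k(t)

decomposes every curve into the population mean mu and orthonormal
eigenfunctions phi_k of the covariance operator, with curve-specific scores

    xi_ik = ∫ (X_i(t) - mu(t)) phi_k(t) dt .

On a grid the integral becomes a quadrature sum with weights w (trapezoid by
default, so unevenly spaced sampling times are handled correctly), and the
eigenproblem is solved for the symmetrised matrix W^{1/2} C W^{1/2}, where C
is the sample covariance of the curves (denominator n−1).  Eigenfunctions are
returned orthonormal under the weighted inner product <f, g>_w = sum_t w_t
f(t) g(t), with the sign fixed so that sum_t w_t phi_k(t) >= 0 (first nonzero
element positive on ties) — score signs are then reproducible across runs and
platforms.

For resilience analysis the first score typically tracks the overall
magnitude of community displacement and the second the timing/shape of the
recovery, so a trajectory is summarised by the pair (xi_1, xi_2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .trajectories import Trajectory, TrajectorySet, TrajectoryError

__all__ = [
    "FPCAError",
    "FPCAModel",
    "fpca_fit",
    "fpca_scores",
    "reconstruct",
    "simulate_family",
    "score_distance_correlation",
    "score_group_summary",
    "quadrature_weights",
]


class FPCAError(ValueError):
    """Invalid input to the functional-PCA routines."""


def quadrature_weights(grid: np.ndarray, scheme: str = "trapezoid") -> np.ndarray:
    """Quadrature weights for integrals over the time grid.

    ``trapezoid`` uses the composite trapezoid rule (falling back to unit
    weights when the grid has fewer than three points); ``uniform`` uses unit
    weights, which makes the decomposition coincide with ordinary matrix PCA
    of the curve matrix.
    """
    grid = np.asarray(grid, dtype=float)
    m = len(grid)
    if scheme == "uniform" or m < 3:
        return np.ones(m)
    if scheme != "trapezoid":
        raise FPCAError(f"unknown weight scheme {scheme!r}")
    w = np.empty(m)
    d = np.diff(grid)
    w[0] = d[0] / 2
    w[-1] = d[-1] / 2
    w[1:-1] = (d[:-1] + d[1:]) / 2
    return w


@dataclass
class FPCAModel:
    """Fitted functional PCA: grid, mean curve, eigenfunctions, spectrum."""

    grid: np.ndarray                 # m increasing times (hours)
    mean_curve: np.ndarray           # mu(t), length m
    eigenfunctions: np.ndarray       # K × m, orthonormal under <.,.>_w
    eigenvalues: np.ndarray          # K, non-increasing, >= 0
    weights: np.ndarray              # quadrature weights, length m
    total_variance: float            # sum_t w_t C(t, t)
    n_fit: int                       # number of trajectories used in fitting

    @property
    def K(self) -> int:
        return self.eigenfunctions.shape[0]

    @property
    def explained_fractions(self) -> np.ndarray:
        """lambda_k / total weighted variance (sums to <= 1 over k <= K)."""
        if self.total_variance <= 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / self.total_variance

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.tolist(),
            "mean_curve": self.mean_curve.tolist(),
            "eigenfunctions": self.eigenfunctions.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "weights": self.weights.tolist(),
            "total_variance": self.total_variance,
            "n_fit": self.n_fit,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FPCAModel":
        return cls(
            grid=np.asarray(d["grid"], dtype=float),
            mean_curve=np.asarray(d["mean_curve"], dtype=float),
            eigenfunctions=np.asarray(d["eigenfunctions"], dtype=float),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
            total_variance=float(d["total_variance"]),
            n_fit=int(d["n_fit"]),
        )


def _curve_matrix_on_grid(ts: TrajectorySet, grid: np.ndarray) -> np.ndarray:
    if len(ts.grid) != len(grid) or not np.allclose(ts.grid, grid):
        raise FPCAError("grid mismatch between trajectory set and model")
    X = ts.curve_matrix()
    if not np.all(np.isfinite(X)):
        raise FPCAError("non-finite distances in trajectory set")
    return X


def fpca_fit(
    ts: TrajectorySet,
    K: int = 2,
    weights: Literal["trapezoid", "uniform"] = "trapezoid",
) -> FPCAModel:
    """Fit the Karhunen–Loève decomposition of a trajectory family.

    Parameters
    ----------
    ts:
        Trajectories, all observed on the common grid.
    K:
        Number of components kept; must satisfy ``K <= min(n - 1, m)``.
    weights:
        Quadrature scheme for the functional inner product.
    """
    n = len(ts)
    if n < 2:
        raise FPCAError("need at least two trajectories to estimate a covariance")
    X = ts.curve_matrix()
    if not np.all(np.isfinite(X)):
        raise FPCAError("non-finite distances in trajectory set")
    m = X.shape[1]
    if not (1 <= K <= min(n - 1, m)):
        raise FPCAError(f"K={K} must lie in [1, min(n-1, m)] = [1, {min(n - 1, m)}]")
    w = quadrature_weights(ts.grid, weights)
    mu = X.mean(axis=0)
    Xc = X - mu
    C = (Xc.T @ Xc) / (n - 1)
    sw = np.sqrt(w)
    M = sw[:, None] * C * sw[None, :]
    evals, evecs = np.linalg.eigh(M)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    phis = (evecs / sw[:, None]).T        # K_full × m, <phi, phi>_w = 1
    # sign convention: positive weighted mass, then first nonzero positive
    scale = np.abs(phis).max() or 1.0
    for k in range(phis.shape[0]):
        s = float(w @ phis[k])
        if abs(s) <= 1e-12 * scale:
            nz = np.nonzero(np.abs(phis[k]) > 1e-12 * scale)[0]
            s = phis[k][nz[0]] if len(nz) else 1.0
        if s < 0:
            phis[k] = -phis[k]
    total = float(w @ np.diag(C))
    return FPCAModel(
        grid=ts.grid.copy(),
        mean_curve=mu,
        eigenfunctions=phis[:K],
        eigenvalues=evals[:K],
        weights=w,
        total_variance=total,
        n_fit=n,
    )


def fpca_scores(model: FPCAModel, ts: TrajectorySet) -> pd.DataFrame:
    """Project trajectories onto the model's eigenfunctions.

    Returns one row per trajectory with columns ``subject_id, condition,
    FPCA1, ..., FPCAK`` where ``FPCAk = sum_t w_t (X_i(t) - mu(t)) phi_k(t)``.
    """
    X = _curve_matrix_on_grid(ts, model.grid)
    Xc = X - model.mean_curve
    xi = (Xc * model.weights) @ model.eigenfunctions.T
    out = pd.DataFrame(ts.labels(), columns=["subject_id", "condition"])
    for k in range(model.K):
        out[f"FPCA{k + 1}"] = xi[:, k]
    return out


def _score_columns(scores: pd.DataFrame) -> list[str]:
    cols = [c for c in scores.columns if c.startswith("FPCA")]
    if not cols:
        raise FPCAError("no FPCA score columns found")
    return sorted(cols, key=lambda c: int(c[4:]))


def reconstruct(model: FPCAModel, scores: pd.DataFrame, N: int) -> TrajectorySet:
    """Rebuild curves from the first ``N`` components, ``mu + sum xi_k phi_k``.

    ``N = 0`` returns the mean curve for every row of ``scores``.
    """
    if not (0 <= N <= model.K):
        raise FPCAError(f"N={N} must lie in [0, K={model.K}]")
    cols = _score_columns(scores)[:N]
    xi = scores[cols].to_numpy(dtype=float) if N else np.zeros((len(scores), 0))
    X = model.mean_curve + xi @ model.eigenfunctions[:N]
    trajectories = [
        Trajectory(str(row.subject_id), str(row.condition), model.grid, X[i])
        for i, row in enumerate(scores.itertuples())
    ]
    return TrajectorySet(trajectories, grid=model.grid.copy())


def simulate_family(
    model: FPCAModel,
    xi1_values: Sequence[float],
    xi2_values: Sequence[float],
) -> TrajectorySet:
    """Synthesize curves on a Cartesian grid of the first two scores.

    One curve ``mu + a*phi_1 + b*phi_2`` is produced per pair ``(a, b)`` in
    ``xi1_values × xi2_values`` (outer loop over ``a``), labelled
    ``subject_id = "xi1=a"``, ``condition = "xi2=b"``.  Varying the two scores
    independently displays the joint repertoire of impact/recovery shapes the
    fitted model can express.
    """
    if model.K < 2:
        raise FPCAError("simulate_family requires a model with K >= 2")
    xi1 = np.asarray(list(xi1_values), dtype=float)
    xi2 = np.asarray(list(xi2_values), dtype=float)
    if xi1.size == 0 or xi2.size == 0:
        raise FPCAError("score grids must be non-empty")
    trajectories = []
    for a in xi1:
        for b in xi2:
            curve = model.mean_curve + a * model.eigenfunctions[0] + b * model.eigenfunctions[1]
            trajectories.append(Trajectory(f"xi1={a:g}", f"xi2={b:g}", model.grid, curve))
    return TrajectorySet(trajectories, grid=model.grid.copy())


def score_distance_correlation(scores: pd.DataFrame, ts: TrajectorySet) -> pd.DataFrame:
    """Pearson correlation of each score with the distance at each grid time.

    Rows are grid times, columns the score names; a cell is NaN when either
    variable is constant across trajectories.  ``scores`` rows must match the
    trajectory labels one-to-one.
    """
    if len(ts) < 3:
        raise FPCAError("need at least three trajectories for correlations")
    labels = [(str(s), str(c)) for s, c in zip(scores["subject_id"], scores["condition"])]
    ts_labels = ts.labels()
    if sorted(labels) != sorted(ts_labels):
        raise FPCAError("score rows and trajectories do not describe the same groups")
    index_of = {lab: i for i, lab in enumerate(ts_labels)}
    X = ts.curve_matrix()[[index_of[lab] for lab in labels]]
    cols = _score_columns(scores)
    out = pd.DataFrame(index=pd.Index(ts.grid, name="time_h"), columns=cols, dtype=float)
    for col in cols:
        s = scores[col].to_numpy(dtype=float)
        s_sd = np.std(s)
        for j, t in enumerate(ts.grid):
            y = X[:, j]
            if s_sd == 0 or np.std(y) == 0:
                out.loc[t, col] = np.nan
            else:
                out.loc[t, col] = float(np.corrcoef(s, y)[0, 1])
    return out


def score_group_summary(scores: pd.DataFrame, by: str = "condition") -> pd.DataFrame:
    """Per-group mean ± sample standard deviation of each score.

    The sd uses the n−1 denominator and is missing (NaN) for singleton
    groups.
    """
    if by not in scores.columns:
        raise FPCAError(f"grouping column {by!r} not in scores")
    cols = _score_columns(scores)
    records = []
    for grp, sub in scores.groupby(by, sort=True):
        for col in cols:
            v = sub[col].to_numpy(dtype=float)
            sd = float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
            records.append((grp, col, float(np.mean(v)), sd, len(v)))
    return pd.DataFrame(records, columns=[by, "score", "mean", "sd", "n"])
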