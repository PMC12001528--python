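"""Synthetic longitudinal microbiome studies with known perturbation truth.

The generator emulates a perturbation–recovery experiment of the kind used to
probe gut-microbiome resilience: a cohort of subjects, each undergoing one or
more challenge conditions, is sampled at a handful of timepoints spanning the
disturbance and the recovery window (default 0, 0.5, 3, 6, 24 and 48 hours).

Mechanism, per (subject, condition) trajectory:

* a subject-specific baseline composition is drawn in CLR space around
  heavy-tailed population log-levels, reproducing the typical unbalanced
  profile in which a few taxa dominate and many are rare;
* the challenge displaces the community along a fixed zero-sum unit direction
  spanning ``shock_direction_dim`` taxa, scaled by a trajectory-specific
  magnitude ``m`` (the *impact*) times a shape ``s(t)`` that rises linearly
  from 0 to 1 at the peak time and then decays exponentially with a
  trajectory-specific half-life ``h`` (the *recovery*):

      clr(t) = clr_baseline + m * s(t) * direction
      s(t)   = t / t_peak                       for t <= t_peak
      s(t)   = 2^{-(t - t_peak) / h}            for t >  t_peak

  Because the direction has unit CLR norm, the noise-free Aitchison distance
  from baseline is exactly ``m * s(t)``, so the generating magnitude and
  half-life are the ground truth that downstream FPCA scores should track;
* optional multinomial resampling at a sequencing depth converts proportions
  to noisy counts, and low-abundance cells are zeroed to reach a target
  sparsity, mimicking the absent-in-most-samples pattern of real 16S tables.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .compositions import AbundanceTable

__all__ = [
    "SynthConfig",
    "generate_study",
    "truth_recovery_report",
    "generate_fpca_family",
]


@dataclass(frozen=True)
class SynthConfig:
    """Study-design and noise parameters of the generator.

    Defaults emulate a 15-subject, three-condition, six-timepoint design with
    a CLR-space shock of around 8 Aitchison units peaking at 4.5 h (inside
    the 3–6 h window where exercise-type disturbances are typically
    strongest) and a recovery half-life of around 12 h.
    """

    n_subjects: int = 15
    conditions: tuple[str, ...] = ("wheel", "atv", "sled")
    n_taxa: int = 100
    times_h: tuple[float, ...] = (0.0, 0.5, 3.0, 6.0, 24.0, 48.0)
    magnitude_mean: float = 8.0
    magnitude_sd: float = 3.0
    recovery_halflife_mean: float = 12.0
    recovery_halflife_sd: float = 4.0
    shock_direction_dim: int = 10
    peak_time_h: float = 4.5
    sequencing_depth: int | None = 50_000
    sparsity_zeros_frac: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.conditions:
            raise ValueError("at least one condition is required")
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        times = tuple(float(t) for t in self.times_h)
        if 0.0 not in times:
            raise ValueError("times_h must include the baseline time 0")
        if len(set(times)) != len(times):
            raise ValueError("times_h must be distinct")
        if self.magnitude_sd < 0 or self.recovery_halflife_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.recovery_halflife_mean <= 0:
            raise ValueError("recovery half-life must be positive")
        if not (0 < self.shock_direction_dim <= self.n_taxa):
            raise ValueError("shock_direction_dim must be in [1, n_taxa]")
        if self.peak_time_h <= 0:
            raise ValueError("peak_time_h must be positive")
        if self.sequencing_depth is not None and self.sequencing_depth < 100:
            raise ValueError("sequencing_depth must be >= 100 (or None)")
        if not (0 <= self.sparsity_zeros_frac < 1):
            raise ValueError("sparsity_zeros_frac must be in [0, 1)")


def _shock_shape(t: float, peak: float, halflife: float) -> float:
    if t <= 0:
        return 0.0
    if t <= peak:
        return t / peak
    return float(2.0 ** (-(t - peak) / halflife))


def _shock_direction(rng: np.random.Generator, n_taxa: int, dim: int) -> np.ndarray:
    """Zero-sum, unit-norm CLR direction supported on ``dim`` random taxa."""
    idx = rng.choice(n_taxa, size=dim, replace=False)
    load = rng.normal(size=dim)
    direction = np.zeros(n_taxa)
    direction[idx] = load
    direction -= direction.mean()          # zero-sum: stays in CLR space
    return direction / np.linalg.norm(direction)


def _sparsify(values: np.ndarray, target_frac: float) -> np.ndarray:
    """Zero the smallest positive cells until the zero fraction reaches target.

    Never empties a row completely.  If the matrix is already sparser than
    the target nothing is changed.
    """
    out = values.copy()
    n_cells = out.size
    quota = int(round(target_frac * n_cells)) - int((out == 0).sum())
    if quota <= 0:
        return out
    rows, cols = np.nonzero(out)
    vals = out[rows, cols]
    order = np.argsort(vals, kind="stable")
    row_pos_counts = (out > 0).sum(axis=1)
    for i in order:
        if quota == 0:
            break
        r, c = rows[i], cols[i]
        if row_pos_counts[r] <= 1:
            continue
        out[r, c] = 0.0
        row_pos_counts[r] -= 1
        quota -= 1
    return out


def generate_study(config: SynthConfig) -> tuple[AbundanceTable, pd.DataFrame, pd.DataFrame]:
    """Generate an abundance table, sample metadata and the generating truth.

    Returns
    -------
    table:
        Samples × taxa counts (or proportions when ``sequencing_depth`` is
        None), one row per subject × condition × timepoint.
    meta:
        Metadata with ``sample_id, subject_id, condition, time_h,
        is_baseline`` (the t=0 sample of each condition is the baseline).
    truth:
        One row per (subject, condition) with the generating shock
        ``magnitude`` and recovery ``halflife``.
    """
    rng = np.random.default_rng(config.seed)
    D = config.n_taxa
    times = tuple(float(t) for t in config.times_h)

    # heavy-tailed population log-levels: a few dominant taxa, many rare ones
    alpha = rng.normal(loc=0.0, scale=2.0, size=D)
    direction = _shock_direction(rng, D, config.shock_direction_dim)

    subjects = [f"S{i + 1:02d}" for i in range(config.n_subjects)]
    taxa = [f"taxon_{j + 1:03d}" for j in range(D)]

    rows, meta_records, truth_records = [], [], []
    sample_index = []
    for subject in subjects:
        base_clr = alpha + rng.normal(scale=0.7, size=D)
        base_clr -= base_clr.mean()
        for condition in config.conditions:
            magnitude = max(0.0, rng.normal(config.magnitude_mean, config.magnitude_sd))
            halflife = max(0.5, rng.normal(config.recovery_halflife_mean, config.recovery_halflife_sd))
            truth_records.append((subject, condition, magnitude, halflife))
            for t in times:
                shift = magnitude * _shock_shape(t, config.peak_time_h, halflife)
                logp = base_clr + shift * direction
                p = np.exp(logp - logp.max())
                p /= p.sum()
                sample_id = f"{subject}_{condition}_t{t:g}"
                sample_index.append(sample_id)
                rows.append(p)
                meta_records.append((sample_id, subject, condition, t, t == 0.0))

    values = np.vstack(rows)
    if config.sequencing_depth is not None:
        counts = np.vstack(
            [rng.multinomial(config.sequencing_depth, p) for p in values]
        ).astype(float)
        values = _sparsify(counts, config.sparsity_zeros_frac)
    else:
        values = _sparsify(values, config.sparsity_zeros_frac)
        values = values / values.sum(axis=1, keepdims=True)

    table = AbundanceTable(pd.DataFrame(values, index=sample_index, columns=taxa))
    meta = pd.DataFrame(
        meta_records,
        columns=["sample_id", "subject_id", "condition", "time_h", "is_baseline"],
    )
    truth = pd.DataFrame(
        truth_records, columns=["subject_id", "condition", "magnitude", "halflife"]
    )
    return table, meta, truth


def generate_fpca_family(
    n: int = 200,
    grid: tuple[float, ...] = (0.0, 0.5, 3.0, 6.0, 24.0, 48.0),
    variances: tuple[float, float] = (4.0, 1.0),
    seed: int = 0,
    weights: str = "trapezoid",
):
    """Noise-free curve family with known components and exact score variances.

    Builds two smooth eigenfunctions orthonormalised under the quadrature
    inner product of ``grid``, draws Gaussian scores and then standardises
    them empirically — exactly zero mean, exactly the requested sample
    variances, exactly zero sample correlation — so the family realises the
    nominal spectrum ``variances`` without Monte-Carlo slack.  A functional
    PCA fitted to the family should recover the components, the explained
    fractions implied by ``variances`` and the individual scores; this is the
    standard parameter-recovery oracle for the FPCA machinery.

    Returns ``(trajectory_set, true_scores, mean_curve, components)`` where
    ``true_scores`` is ``n × 2`` and ``components`` is ``2 × m``.
    """
    from .fpca import quadrature_weights
    from .trajectories import Trajectory, TrajectorySet

    grid_arr = np.asarray(grid, dtype=float)
    m = len(grid_arr)
    if m < 3:
        raise ValueError("grid needs at least three points")
    w = quadrature_weights(grid_arr, weights)
    span = grid_arr[-1] - grid_arr[0]
    # smooth raw shapes: a decaying bump and a late-recovery contrast
    raw1 = np.exp(-grid_arr / (span / 3.0)) * (grid_arr / span + 0.2)
    raw2 = np.cos(np.pi * grid_arr / span)
    phi1 = raw1 / np.sqrt(w @ raw1**2)
    raw2 = raw2 - (w @ (raw2 * phi1)) * phi1          # Gram-Schmidt under <.,.>_w
    phi2 = raw2 / np.sqrt(w @ raw2**2)
    mu = 5.0 + 4.0 * np.sin(np.pi * grid_arr / span)

    rng = np.random.default_rng(seed)
    xi = rng.normal(size=(n, 2))
    xi -= xi.mean(axis=0)
    cov = (xi.T @ xi) / (n - 1)
    xi = xi @ np.linalg.inv(np.linalg.cholesky(cov)).T   # whiten empirically
    xi *= np.sqrt(np.asarray(variances))

    curves = mu + xi[:, [0]] * phi1 + xi[:, [1]] * phi2
    trajectories = [
        Trajectory(f"curve_{i:04d}", "sim", grid_arr, curves[i]) for i in range(n)
    ]
    ts = TrajectorySet(trajectories, grid=grid_arr.copy())
    return ts, xi, mu, np.vstack([phi1, phi2])


def truth_recovery_report(truth: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlations between generating parameters and FPCA scores.

    Reports ``rho(magnitude, FPCA1)`` and, when a second score is present,
    ``rho(halflife, FPCA2)``, with signs.  Rows of ``truth`` and ``scores``
    are aligned on (subject_id, condition); a constant variable yields a
    missing correlation.
    """
    from scipy.stats import spearmanr

    merged = truth.merge(scores, on=["subject_id", "condition"], how="outer", indicator=True)
    if (merged["_merge"] != "both").any():
        bad = merged.loc[merged["_merge"] != "both", ["subject_id", "condition"]]
        raise ValueError(
            f"truth and scores are misaligned on: {bad.to_records(index=False).tolist()}"
        )
    pairs = [("magnitude", "FPCA1")]
    if "FPCA2" in merged.columns and "halflife" in merged.columns:
        pairs.append(("halflife", "FPCA2"))
    records = []
    for truth_col, score_col in pairs:
        x = merged[truth_col].to_numpy(dtype=float)
        y = merged[score_col].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            rho = float("nan")
        else:
            rho = float(spearmanr(x, y).statistic)
        records.append((truth_col, score_col, rho, len(merged)))
    return pd.DataFrame(records, columns=["truth_parameter", "score", "spearman_rho", "n"])
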