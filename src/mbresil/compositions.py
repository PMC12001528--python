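"""Compositional primitives: closure, zero replacement, CLR, Aitchison distance.

Relative-abundance vectors are *compositions*: only the ratios between parts
carry information, not the absolute scale.  The natural geometry for such data
is Aitchison geometry, in which a composition ``u = (u_1, ..., u_D)`` is mapped
to Euclidean space by the centred log-ratio (CLR) transform

    clr(u)_k = log(u_k / g(u)),          g(u) = geometric mean of u,

and the Aitchison distance between two compositions is the Euclidean distance
of their CLR images,

    d(u, v) = || clr(u) - clr(v) ||_2 .

This distance is scale-invariant, permutation-equivariant, and consistent
under taking subcompositions — properties that divergences such as
Jensen–Shannon lack.  It is, however, undefined in the presence of zeros, so
count tables must first pass through :func:`replace_zeros`.

Natural logarithms are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompositionError",
    "AbundanceTable",
    "ZeroReplacementParams",
    "close",
    "replace_zeros",
    "clr",
    "aitchison_distance",
]

#: tolerance used when deciding whether a row already sums to one
CLOSURE_TOL = 1e-6


class CompositionError(ValueError):
    """An input violates a compositional contract (zeros, negatives, shape)."""


class AbundanceTable:
    """A samples × taxa matrix of non-negative abundances.

    Wraps a :class:`pandas.DataFrame` whose index holds sample identifiers and
    whose columns hold taxon identifiers.  Values may be counts or relative
    abundances; :meth:`close` converts rows to proportions.

    Raises
    ------
    CompositionError
        If any entry is negative, any row is entirely zero, any value is
        non-finite, or sample/taxon identifiers are duplicated.
    """

    def __init__(self, data: pd.DataFrame):
        if not isinstance(data, pd.DataFrame):
            raise CompositionError("AbundanceTable expects a pandas DataFrame")
        if data.shape[0] == 0 or data.shape[1] == 0:
            raise CompositionError("abundance table must have at least one sample and one taxon")
        values = data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise CompositionError("abundance table contains non-finite values")
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise CompositionError(
                f"negative abundance at sample {data.index[bad[0]]!r}, "
                f"taxon {data.columns[bad[1]]!r}"
            )
        row_sums = values.sum(axis=1)
        if (row_sums <= 0).any():
            empty = [str(s) for s in data.index[row_sums <= 0]]
            raise CompositionError(f"sample(s) with zero total abundance: {empty}")
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise CompositionError(f"duplicate sample id(s): {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise CompositionError(f"duplicate taxon id(s): {dups}")
        self._data = data.astype(float).copy()
        self._data.index = self._data.index.astype(str)
        self._data.columns = self._data.columns.astype(str)

    # -- basic accessors -------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def values(self) -> np.ndarray:
        return self._data.to_numpy()

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self._data.columns)

    @property
    def n_samples(self) -> int:
        return self._data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self._data.shape[1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"AbundanceTable({self.n_samples} samples × {self.n_taxa} taxa)"

    # -- derived views ---------------------------------------------------
    def is_closed(self, tol: float = CLOSURE_TOL) -> bool:
        """True when every row sums to one within ``tol``."""
        return bool(np.all(np.abs(self.values.sum(axis=1) - 1.0) <= tol))

    def is_strictly_positive(self) -> bool:
        return bool((self.values > 0).all())

    def close(self) -> "AbundanceTable":
        """Return a copy with every row rescaled to sum to one."""
        closed = self._data.div(self._data.sum(axis=1), axis=0)
        return AbundanceTable(closed)

    def min_positive_proportion(self) -> float:
        """Smallest nonzero entry of the row-closed table."""
        p = self.close().values
        return float(p[p > 0].min())


@dataclass(frozen=True)
class ZeroReplacementParams:
    """Configuration of the zero-replacement step.

    ``multiplicative`` substitutes each zero (on the proportion scale) with a
    small ``delta`` and shrinks the nonzero parts of the row multiplicatively
    so the row still sums to one.  ``bayes_multiplicative`` draws the imputed
    value from the posterior expectation of a multinomial model with a uniform
    (Bayes–Laplace) prior, which requires count data.

    ``delta="auto"`` resolves to ``0.65 ×`` the smallest nonzero proportion in
    the table, a widely used convention.
    """

    method: Literal["multiplicative", "bayes_multiplicative"] = "multiplicative"
    delta: float | str = "auto"

    def __post_init__(self):
        if self.method not in ("multiplicative", "bayes_multiplicative"):
            raise CompositionError(f"unknown zero-replacement method {self.method!r}")
        if isinstance(self.delta, str):
            if self.delta != "auto":
                raise CompositionError("delta must be a positive number or 'auto'")
        elif not (float(self.delta) > 0):
            raise CompositionError("delta must be positive")


def close(row: Sequence[float] | np.ndarray) -> np.ndarray:
    """Rescale a non-negative vector so its entries sum to one.

    Raises
    ------
    CompositionError
        For an all-zero vector ("empty composition") or negative entries.
    """
    x = np.asarray(row, dtype=float)
    if x.ndim != 1:
        raise CompositionError("close expects a 1-D vector")
    if not np.all(np.isfinite(x)):
        raise CompositionError("non-finite entries")
    if (x < 0).any():
        raise CompositionError("negative entries are not a composition")
    total = x.sum()
    if total <= 0:
        raise CompositionError("empty composition: all entries are zero")
    return x / total


def replace_zeros(
    table: AbundanceTable,
    params: ZeroReplacementParams | None = None,
) -> AbundanceTable:
    """Impute zeros so every entry is strictly positive; rows stay closed.

    The table is first converted to proportions.  Under the multiplicative
    method a row with ``z`` zeros becomes::

        x_j -> delta            if x_j == 0
        x_j -> x_j * (1 - z * delta)   otherwise

    Rows without zeros are returned unchanged (up to closure).

    Raises
    ------
    CompositionError
        If ``z * delta >= 1`` for some row ("delta too large"), if an explicit
        delta is not below the smallest nonzero proportion, or (Bayesian
        variant) if the table does not hold counts.
    """
    params = params or ZeroReplacementParams()
    raw = table.values
    p = raw / raw.sum(axis=1, keepdims=True)
    zero_mask = p == 0
    if not zero_mask.any():
        return table.close()

    if params.method == "multiplicative":
        if params.delta == "auto":
            delta = 0.65 * float(p[p > 0].min())
        else:
            delta = float(params.delta)
            min_pos = float(p[p > 0].min())
            if delta >= min_pos:
                raise CompositionError(
                    f"delta {delta} must lie below the smallest nonzero proportion {min_pos}"
                )
        z = zero_mask.sum(axis=1)
        shrink = 1.0 - z * delta
        if (shrink <= 0).any():
            bad = [str(s) for s in np.asarray(table.sample_ids)[shrink <= 0]]
            raise CompositionError(f"delta too large: z*delta >= 1 for sample(s) {bad}")
        out = p * shrink[:, None]
        out[zero_mask] = delta
    else:  # bayes_multiplicative
        totals = raw.sum(axis=1)
        if np.all(np.abs(totals - 1.0) <= CLOSURE_TOL):
            raise CompositionError(
                "bayes_multiplicative requires count data (row totals > 1)"
            )
        D = table.n_taxa
        # Bayes-Laplace posterior mean for a zero count: 1 / (n_i + D)
        delta_rows = 1.0 / (totals + D)
        out = p.copy()
        replaced = zero_mask * delta_rows[:, None]
        shrink = 1.0 - replaced.sum(axis=1)
        if (shrink <= 0).any():
            bad = [str(s) for s in np.asarray(table.sample_ids)[shrink <= 0]]
            raise CompositionError(f"delta too large: imputed mass >= 1 for sample(s) {bad}")
        out = p * shrink[:, None]
        out[zero_mask] = (np.broadcast_to(delta_rows[:, None], p.shape))[zero_mask]

    frame = pd.DataFrame(out, index=table.sample_ids, columns=table.taxon_ids)
    return AbundanceTable(frame)


def clr(composition: Sequence[float] | np.ndarray) -> np.ndarray:
    """Centred log-ratio transform of one composition or a stack of them.

    Accepts a 1-D vector or a 2-D (rows = compositions) array of strictly
    positive values; closure is not required because CLR is scale-invariant.
    Components of each output row sum to zero.
    """
    x = np.asarray(composition, dtype=float)
    if x.ndim not in (1, 2):
        raise CompositionError("clr expects a 1-D or 2-D array")
    if not np.all(np.isfinite(x)):
        raise CompositionError("non-finite entries")
    if (x <= 0).any():
        raise CompositionError("zeros must be replaced before CLR")
    logx = np.log(x)
    return logx - logx.mean(axis=-1, keepdims=True)


def aitchison_distance(u: Sequence[float], v: Sequence[float]) -> float:
    """Aitchison distance between two strictly positive abundance vectors.

    Equals the Euclidean norm of ``clr(u) - clr(v)``; closure of the inputs is
    not required (the distance is scale-invariant).
    """
    a = np.asarray(u, dtype=float)
    b = np.asarray(v, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise CompositionError("aitchison_distance expects 1-D vectors")
    if a.shape != b.shape:
        raise CompositionError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    if a.shape[0] < 2:
        raise CompositionError("compositions need at least two parts")
    return float(np.linalg.norm(clr(a) - clr(b)))
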