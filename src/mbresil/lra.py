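"""Log-ratio analysis (LRA): variance decomposition over taxa and selection.

LRA is the weighted principal component analysis of the log-transformed
composition matrix, double-centred with uniform row weights ``r_i = 1/n`` and
the compositional part means ``c_j`` (mean closed abundance of taxon ``j``) as
column weights.  Writing ``l_ij = log p_ij``:

    a_ij = l_ij - sum_j c_j l_ij        (row-centring: weighted CLR)
    y_ij = a_ij - sum_i r_i a_ij        (column-centring)

    total variance  = sum_ij r_i c_j y_ij^2
    contribution_j  = sum_i  r_i c_j y_ij^2 / total variance

The per-taxon contributions sum to one and rank taxa by their share of the
total log-ratio variance, independently of their average abundance; a
low-abundance taxon is selected whenever its ratios vary enough.  The total
variance obeys the classical identity

    total = 1/2 * sum_jk c_j c_k Var_n( log(p_j / p_k) )

(population variance over samples), which the test suite uses as a
brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compositions import AbundanceTable, CompositionError

__all__ = ["LRAResult", "lra_fit", "select_taxa", "subset_and_reclose"]


@dataclass
class LRAResult:
    """Variance decomposition of a strictly positive abundance table."""

    taxon_ids: list[str]
    contributions: np.ndarray          # per taxon, sums to 1
    total_variance: float
    row_weights: np.ndarray            # uniform 1/n
    column_weights: np.ndarray         # part means, sums to 1
    centered_matrix: np.ndarray        # y_ij, n × D

    def ranked(self) -> pd.DataFrame:
        """Taxa with contributions, sorted by decreasing contribution.

        Ties are broken lexicographically by taxon id so the ranking is
        deterministic.
        """
        df = pd.DataFrame(
            {"taxon_id": self.taxon_ids, "contribution": self.contributions}
        )
        df = df.sort_values(
            ["contribution", "taxon_id"], ascending=[False, True], kind="mergesort"
        )
        return df.reset_index(drop=True)


def lra_fit(table: AbundanceTable) -> LRAResult:
    """Decompose the total log-ratio variance of a table over its taxa.

    The table must be strictly positive (run zero replacement first); rows
    are closed internally if needed.

    Raises
    ------
    CompositionError
        If zeros are present, fewer than two samples exist, or the table has
        no compositional variation (all rows identical).
    """
    if not table.is_strictly_positive():
        raise CompositionError("zeros present: run replace_zeros before lra_fit")
    if table.n_samples < 2:
        raise CompositionError("lra_fit needs at least two samples")
    p = table.values
    p = p / p.sum(axis=1, keepdims=True)
    n, D = p.shape
    r = np.full(n, 1.0 / n)
    c = p.mean(axis=0)
    c = c / c.sum()
    l = np.log(p)
    a = l - (l @ c)[:, None]
    y = a - r @ a
    cell = (r[:, None] * c[None, :]) * y**2
    total = float(cell.sum())
    if total <= 1e-14:
        raise CompositionError("no compositional variation among samples")
    contributions = cell.sum(axis=0) / total
    return LRAResult(
        taxon_ids=table.taxon_ids,
        contributions=contributions,
        total_variance=total,
        row_weights=r,
        column_weights=c,
        centered_matrix=y,
    )


def select_taxa(result: LRAResult, threshold: float = 0.9) -> list[str]:
    """Shortest prefix of contribution-ranked taxa reaching ``threshold``.

    Taxa are sorted by decreasing contribution (ties broken by taxon id);
    the returned list is the minimal prefix whose cumulative contribution
    is at least ``threshold``.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ranked = result.ranked()
    cum = ranked["contribution"].cumsum().to_numpy()
    # small slack so e.g. cumulative 0.9 satisfies threshold 0.9 despite rounding
    k = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    k = min(k, len(ranked))
    return ranked["taxon_id"].head(k).tolist()


def subset_and_reclose(table: AbundanceTable, taxa: list[str]) -> AbundanceTable:
    """Restrict a table to ``taxa`` and re-close each row to sum to one.

    Column order follows ``taxa``.  Raises if a requested taxon is absent or
    if any sample has no positive abundance left on the subset.
    """
    missing = [t for t in taxa if t not in table.data.columns]
    if missing:
        raise CompositionError(f"taxa not in table: {missing}")
    if len(set(taxa)) != len(taxa):
        raise CompositionError("duplicate taxa in subset")
    sub = table.data[list(taxa)]
    sums = sub.sum(axis=1)
    dead = sub.index[sums <= 0].tolist()
    if dead:
        raise CompositionError(
            f"sample(s) with zero abundance on the subset: {dead}"
        )
    return AbundanceTable(sub.div(sums, axis=0))
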