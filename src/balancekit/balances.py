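"""Balance scores, variance decomposition, and ranking.

The balance of sample x for an SBP column with r positively and s
negatively signed parts is

    b = sqrt(r*s / (r+s)) * ln( g(x over + parts) / g(x over - parts) )

with g the geometric mean. Because the D-1 contrasts of a full SBP form an
orthonormal basis of the clr plane, the sample-wise variances of the
balances sum exactly to the total clr variance — the decomposition that
justifies ranking balances by the proportion of variance they explain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (AlignmentError, BalanceLookupError, ClrTable,
                   CompositionTable, DomainError)
from .sbp import SbpMatrix, sbp_to_contrast

__all__ = [
    "BalanceTable",
    "compute_balances",
    "variance_decomposition",
    "rank_balances",
    "subset_balances",
]

SUMMARY_COLUMNS = ["variance", "proportion_of_total_variance",
                   "min", "max", "median"]


@dataclass(frozen=True)
class BalanceTable:
    """Samples x balances score matrix with a per-balance summary.

    ``summary`` rows are indexed by balance id and carry the unbiased
    sample variance, the proportion of the total clr variance explained
    (denominator always from the full D-1 balance decomposition, even in
    subset tables), and the min/max/median of the scores.
    """

    scores: pd.DataFrame
    summary: pd.DataFrame

    @property
    def sample_ids(self) -> list:
        return list(self.scores.index)

    @property
    def balance_ids(self) -> list:
        return list(self.scores.columns)

    @property
    def values(self) -> np.ndarray:
        return self.scores.to_numpy(dtype=float)


def _summarize(scores: pd.DataFrame, total_variance: float) -> pd.DataFrame:
    var = scores.var(axis=0, ddof=1)
    return pd.DataFrame({
        "variance": var,
        "proportion_of_total_variance": var / total_variance
        if total_variance > 0 else np.nan,
        "min": scores.min(axis=0),
        "max": scores.max(axis=0),
        "median": scores.median(axis=0),
    }, index=scores.columns)[SUMMARY_COLUMNS]


def compute_balances(data: CompositionTable, sbp: SbpMatrix) -> BalanceTable:
    """Compute every balance score of a composition table under an SBP.

    Components are matched by label (order-insensitive); the data must be
    strictly positive. Scores are computed by the explicit geometric-mean
    formula; the contrast-matrix route ``Psi @ ln(x)`` gives the same
    numbers and serves as an independent cross-check in the test suite.
    """
    if data.has_zeros:
        raise DomainError(
            "composition contains zeros; apply replace_zeros before "
            "computing balances"
        )
    data_comps = set(data.component_ids)
    sbp_comps = set(sbp.component_ids)
    if data_comps != sbp_comps:
        raise AlignmentError(
            "component labels of data and SBP differ; "
            f"only in data: {sorted(data_comps - sbp_comps)[:5]}, "
            f"only in SBP: {sorted(sbp_comps - data_comps)[:5]}"
        )
    logs = np.log(data.data[sbp.component_ids].to_numpy(dtype=float))
    signs = sbp.signs.to_numpy(dtype=float)  # D x (D-1)
    plus = (signs == 1)
    minus = (signs == -1)
    r = plus.sum(axis=0).astype(float)
    s = minus.sum(axis=0).astype(float)
    coef = np.sqrt(r * s / (r + s))
    # log of geometric mean over each side = mean of logs over that side
    log_gp = logs @ plus / r
    log_gn = logs @ minus / s
    scores = coef * (log_gp - log_gn)
    scores_df = pd.DataFrame(scores, index=data.data.index,
                             columns=sbp.signs.columns)
    if scores_df.shape[0] >= 2:
        total = float(scores_df.var(axis=0, ddof=1).sum())
    else:
        total = 0.0
    return BalanceTable(scores=scores_df,
                        summary=_summarize(scores_df, total))


def variance_decomposition(balances: BalanceTable,
                           clr_data: ClrTable) -> pd.DataFrame:
    """Per-balance variance, proportion of total, and the conservation check.

    For a full SBP the total of the balance variances equals the total clr
    variance. Returns a DataFrame indexed by balance id with columns
    ``variance`` and ``proportion``, plus attrs ``total_balance_variance``
    and ``total_clr_variance``.
    """
    if balances.scores.shape[0] < 2:
        raise DomainError("variance decomposition needs at least 2 samples")
    if set(balances.sample_ids) != set(clr_data.sample_ids):
        raise AlignmentError("balance and clr tables cover different samples")
    if balances.scores.shape[1] != len(clr_data.component_ids) - 1:
        raise DomainError(
            "variance decomposition requires a complete SBP "
            f"(expected {len(clr_data.component_ids) - 1} balances, "
            f"got {balances.scores.shape[1]})"
        )
    var = balances.scores.var(axis=0, ddof=1)
    total = float(var.sum())
    out = pd.DataFrame({"variance": var, "proportion": var / total})
    out.attrs["total_balance_variance"] = total
    out.attrs["total_clr_variance"] = float(
        clr_data.data.var(axis=0, ddof=1).sum()
    )
    return out


def rank_balances(balances: BalanceTable, k: int) -> list:
    """Ids of the k balances with the largest sample variance, descending.

    Exact variance ties are broken by original column order (stable sort).
    The returned subset is typically passed through
    :func:`balancekit.sbp.order_balances` for display.
    """
    m = len(balances.balance_ids)
    if not (isinstance(k, (int, np.integer)) and 0 < k <= m):
        raise DomainError(f"k must be an integer in [1, {m}], got {k!r}")
    var = balances.scores.var(axis=0, ddof=1)
    order = np.argsort(-var.to_numpy(), kind="stable")
    return [balances.balance_ids[i] for i in order[:k]]


def subset_balances(balances: BalanceTable, ids) -> BalanceTable:
    """Project a balance table onto a subset of balance ids.

    Scores are taken verbatim from the full table, and the summary keeps the
    proportions computed against the FULL decomposition, so subsetting never
    changes the interpretation of the retained balances.
    """
    ids = list(ids)
    if not ids:
        raise DomainError("balance subset must be non-empty")
    unknown = [b for b in ids if b not in balances.scores.columns]
    if unknown:
        raise BalanceLookupError(f"unknown balance ids: {unknown}")
    return BalanceTable(scores=balances.scores[ids],
                        summary=balances.summary.loc[ids])
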