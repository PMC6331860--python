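"""Kendall coefficient of concordance over recall tables.

Each activity class acts as a judge (rater) ranking the similarity methods
(objects) by its recall value; Kendall's W in ``[0, 1]`` measures how much
the classes agree.  Ties within a class receive midranks and the standard
``(t^3 - t)`` correction; significance comes from the chi-square
approximation ``X^2 = m (n - 1) W`` on ``n - 1`` degrees of freedom.  The
rank sums also induce an overall ordering of the methods, rendered as a
string like ``"A = B > C"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ConcordanceResult", "kendall_w", "ranking_string"]


@dataclass(frozen=True)
class ConcordanceResult:
    """Kendall W with its chi-square test and the induced method ranking."""

    W: float
    chi2: float
    df: int
    p: float
    ranking: str
    rank_sums: Mapping[str, float]


def _rank_sum_key(value: float) -> float:
    # midranks are multiples of 1/2, so rank sums are too; rounding guards
    # against float noise when grouping exact ties
    return round(value * 2) / 2


def ranking_string(
    rank_sums: Mapping[str, float],
    mean_scores: Mapping[str, float] | None = None,
) -> str:
    """Order objects by ascending rank sum; '=' joins exact ties, '>' the rest.

    Objects with exactly equal rank sums are displayed best-mean-score first
    when ``mean_scores`` is given, otherwise alphabetically; either way they
    are joined with '='.
    """
    if not rank_sums:
        raise ValueError("rank sums are empty")
    if mean_scores is None:
        key = lambda kv: (_rank_sum_key(kv[1]), kv[0])
    else:
        key = lambda kv: (_rank_sum_key(kv[1]), -mean_scores.get(kv[0], 0.0), kv[0])
    items = sorted(rank_sums.items(), key=key)
    parts = [items[0][0]]
    for (prev_name, prev), (name, cur) in zip(items, items[1:]):
        sep = " = " if _rank_sum_key(cur) == _rank_sum_key(prev) else " > "
        parts.append(sep + name)
    return "".join(parts)


def kendall_w(score_matrix) -> ConcordanceResult:
    """Tie-corrected Kendall coefficient of concordance.

    ``score_matrix`` is a raters x objects table (DataFrame or 2-D array);
    within each rater's row the highest score gets rank 1 and tied scores
    get midranks.  With rank sums ``R_j``, rater tie terms
    ``T_i = sum (t^3 - t)`` and ``m`` raters of ``n`` objects:

        W = (12 sum R_j^2 - 3 m^2 n (n+1)^2) / (m^2 (n^3 - n) - m sum T_i)

    ``X^2 = m (n - 1) W`` is referred to a chi-square distribution with
    ``n - 1`` degrees of freedom.  A constant row (full tie) is legal.
    """
    if isinstance(score_matrix, pd.DataFrame):
        objects = [str(c) for c in score_matrix.columns]
        values = score_matrix.to_numpy(dtype=float)
    else:
        values = np.asarray(score_matrix, dtype=float)
        objects = [f"obj{i}" for i in range(values.shape[1])] if values.ndim == 2 else []
    if values.ndim != 2:
        raise ValueError("score matrix must be two-dimensional (raters x objects)")
    m, n = values.shape
    if m < 2 or n < 2:
        raise ValueError(f"need at least 2 raters and 2 objects, got {m} x {n}")
    if np.isnan(values).any():
        raise ValueError("score matrix has missing cells")

    ranks = np.apply_along_axis(sps.rankdata, 1, -values)  # rank 1 = best
    rank_sums = ranks.sum(axis=0)
    tie_term = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float((counts**3 - counts).sum())

    numerator = 12.0 * float((rank_sums**2).sum()) - 3.0 * m**2 * n * (n + 1) ** 2
    denominator = m**2 * (n**3 - n) - m * tie_term
    if denominator <= 0:
        # every rater fully tied: no dispersion is expressible, define W = 0
        w = 0.0
    else:
        w = numerator / denominator
    w = float(min(max(w, 0.0), 1.0))
    chi2 = m * (n - 1) * w
    df = n - 1
    p = float(sps.chi2.sf(chi2, df))
    sums = {obj: float(s) for obj, s in zip(objects, rank_sums)}
    means = {obj: float(mu) for obj, mu in zip(objects, values.mean(axis=0))}
    return ConcordanceResult(
        W=w, chi2=float(chi2), df=df, p=p,
        ranking=ranking_string(sums, means), rank_sums=sums,
    )
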