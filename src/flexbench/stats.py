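"""Benchmark-level inference on correlation-coefficient tables.

A benchmark run produces, for every protein, one Pearson (r_p) and one
Spearman (r_s) coefficient per flexibility-prediction method.  Two
questions are asked of that table:

* does prediction quality depend on the prediction method and/or on the
  protein's secondary-structure class?  Answered by a fixed-effects
  two-way ANOVA with interaction, run separately per structure-
  determination method (NMR vs X-ray) because the two kinds of
  experimental profile measure physically different things.  Type II sums
  of squares are used so that unbalanced class sizes are handled
  correctly.
* which pairs of methods differ significantly?  Answered by Student's
  t-tests on per-protein coefficient differences (paired by default,
  since the same proteins are scored under every method), summarized in a
  signed significance matrix: upper triangle r_p, lower triangle r_s,
  each cell positive/negative-significant at alpha or not significant.

The input table is a tidy :class:`pandas.DataFrame` with columns
``protein_id``, ``expt_method`` (nmr|xray), ``ss_class``
(alpha|beta|alpha_beta), ``method`` and the responses ``r_p``, ``r_s``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DesignError, UndefinedStatisticError

__all__ = [
    "SignificanceMatrix",
    "two_way_anova",
    "pairwise_t",
    "significance_matrix",
]

POSITIVE = "positive_significant"
NEGATIVE = "negative_significant"
NOT_SIG = "not_significant"


def _filter(
    table: pd.DataFrame,
    expt_method: str | None = None,
    ss_class: str | None = None,
) -> pd.DataFrame:
    out = table
    if expt_method is not None:
        out = out[out["expt_method"] == expt_method]
    if ss_class is not None:
        out = out[out["ss_class"] == ss_class]
    return out


def _dummies(labels: pd.Series) -> np.ndarray:
    """Treatment-coded dummy columns (first level dropped)."""
    levels = sorted(labels.unique())
    return np.column_stack(
        [(labels == lv).to_numpy(float) for lv in levels[1:]]
    ) if len(levels) > 1 else np.empty((len(labels), 0))


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares of an OLS fit and the model's rank."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def two_way_anova(
    table: pd.DataFrame,
    response: str = "r_p",
    expt_method: str | None = None,
) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA (method x ss_class) with interaction.

    Type II sums of squares: each main effect is tested against the model
    containing the other main effect, and the interaction against the
    additive model.  Returns a frame with rows ``method``, ``ss_class``,
    ``interaction`` and ``residual`` and columns ``sum_sq``, ``df``, ``F``,
    ``p``.

    Raises :class:`DesignError` for degenerate designs (a factor with one
    level, zero residual degrees of freedom, or constant response).
    """
    data = _filter(table, expt_method=expt_method)
    if data.empty:
        raise DesignError("no observations after filtering")
    y = data[response].to_numpy(float)
    if np.ptp(y) == 0.0:
        raise DesignError("response is constant; all sums of squares vanish")
    a = _dummies(data["method"])
    b = _dummies(data["ss_class"])
    if a.shape[1] == 0 or b.shape[1] == 0:
        raise DesignError("each factor needs at least 2 levels")
    n = len(y)
    ones = np.ones((n, 1))
    inter = np.column_stack(
        [a[:, i] * b[:, j] for i in range(a.shape[1]) for j in range(b.shape[1])]
    )
    X_a = np.hstack([ones, a])
    X_b = np.hstack([ones, b])
    X_ab = np.hstack([ones, a, b])
    X_full = np.hstack([ones, a, b, inter])

    rss_a, _ = _rss(X_a, y)
    rss_b, _ = _rss(X_b, y)
    rss_ab, rank_ab = _rss(X_ab, y)
    rss_full, rank_full = _rss(X_full, y)
    _, rank_a = _rss(X_a, y)
    _, rank_b = _rss(X_b, y)

    ss = {
        "method": rss_b - rss_ab,
        "ss_class": rss_a - rss_ab,
        "interaction": rss_ab - rss_full,
    }
    df = {
        "method": rank_ab - rank_b,
        "ss_class": rank_ab - rank_a,
        "interaction": rank_full - rank_ab,
    }
    df_resid = n - rank_full
    if df_resid <= 0:
        raise DesignError("zero residual degrees of freedom")
    ms_resid = rss_full / df_resid

    rows = []
    for name in ("method", "ss_class", "interaction"):
        if df[name] <= 0:
            raise DesignError(f"factor {name!r} has no estimable degrees of freedom")
        F = (ss[name] / df[name]) / ms_resid
        p = float(sps.f.sf(F, df[name], df_resid))
        rows.append((name, ss[name], df[name], F, p))
    rows.append(("residual", rss_full, df_resid, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["factor", "sum_sq", "df", "F", "p"]).set_index(
        "factor"
    )


def pairwise_t(
    table: pd.DataFrame,
    method_a: str,
    method_b: str,
    response: str = "r_p",
    expt_method: str | None = None,
    ss_class: str | None = None,
    paired: bool = True,
    equal_var: bool = True,
) -> tuple[float, int, float]:
    """Student's t-test comparing two prediction methods.

    With ``paired=True`` (default; the same proteins are scored under both
    methods) the test is on per-protein differences ``A - B``: returns
    ``(t, df, p)`` with ``df = n - 1`` and a two-sided p-value.  An
    identically zero difference vector yields ``(0, n-1, 1)``; a nonzero
    constant difference has no variance to test against and raises
    :class:`UndefinedStatisticError`.
    """
    data = _filter(table, expt_method=expt_method, ss_class=ss_class)
    xa = data[data["method"] == method_a].set_index("protein_id")[response]
    xb = data[data["method"] == method_b].set_index("protein_id")[response]
    shared = xa.index.intersection(xb.index)
    if len(shared) < 3:
        raise UndefinedStatisticError(
            f"need at least 3 shared proteins, found {len(shared)}"
        )
    va = xa.loc[shared].to_numpy(float)
    vb = xb.loc[shared].to_numpy(float)
    if not paired:
        res = sps.ttest_ind(va, vb, equal_var=equal_var)
        return float(res.statistic), int(np.floor(res.df)), float(res.pvalue)
    d = va - vb
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return 0.0, n - 1, 1.0
        raise UndefinedStatisticError("zero-variance nonzero differences")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return float(t), n - 1, p


@dataclass
class SignificanceMatrix:
    """Signed pairwise significance grid over prediction methods.

    ``labels[i, j]`` for ``i != j`` classifies the mean difference
    ``methods[i] - methods[j]`` (row minus column) as positive/negative
    significant at ``alpha`` or not significant; the upper triangle is
    evaluated on r_p and the lower on r_s.  ``pvalues`` holds the matching
    two-sided p-values.
    """

    methods: list[str]
    labels: np.ndarray
    pvalues: np.ndarray
    alpha: float

    def cell(self, method_a: str, method_b: str) -> tuple[str, float]:
        i = self.methods.index(method_a)
        j = self.methods.index(method_b)
        return self.labels[i, j], float(self.pvalues[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.labels, index=self.methods, columns=self.methods)


def significance_matrix(
    table: pd.DataFrame,
    methods: list[str] | None = None,
    alpha: float = 0.05,
    expt_method: str | None = None,
    ss_class: str | None = None,
    paired: bool = True,
) -> SignificanceMatrix:
    """Pairwise signed significance matrix (upper triangle r_p, lower r_s)."""
    if methods is None:
        methods = sorted(table["method"].unique())
    if len(methods) < 2:
        raise DesignError("need at least 2 methods")
    m = len(methods)
    labels = np.full((m, m), "", dtype=object)
    pvals = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            response = "r_p" if i < j else "r_s"
            t, _, p = pairwise_t(
                table,
                methods[i],
                methods[j],
                response=response,
                expt_method=expt_method,
                ss_class=ss_class,
                paired=paired,
            )
            if p < alpha and t > 0:
                labels[i, j] = POSITIVE
            elif p < alpha and t < 0:
                labels[i, j] = NEGATIVE
            else:
                labels[i, j] = NOT_SIG
            pvals[i, j] = p
    return SignificanceMatrix(
        methods=list(methods), labels=labels, pvalues=pvals, alpha=alpha
    )
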