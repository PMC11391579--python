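"""Profile-agreement and distribution statistics.

Two fluctuation profiles over the same residues are compared with the
Pearson product-moment correlation

    r_p = sum (x_i - xbar)(y_i - ybar) / sqrt(sum (x_i - xbar)^2 sum (y_i - ybar)^2)

and the Spearman rank correlation, which without ties reduces to

    r_s = 1 - 6 sum d_i^2 / (n (n^2 - 1))

with ``d_i`` the per-residue rank difference; with ties it is the Pearson
correlation of average ranks.  Distribution shape over a benchmark is
summarized by the moment skewness g1 = m3 / m2^(3/2), 0.1-wide histograms
on [-1, 1], and the cumulative counting function "number of values not
exceeding x".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .exceptions import AlignmentError, UndefinedStatisticError
from .profiles import FluctProfile

__all__ = [
    "ProfilePair",
    "pearson",
    "spearman",
    "skewness",
    "histogram_counts",
    "cumulative_counts",
    "count_not_exceeding",
]


@dataclass
class ProfilePair:
    """A predicted and an experimental profile matched residue-by-residue."""

    predicted: FluctProfile
    experimental: FluctProfile

    def __post_init__(self) -> None:
        if not np.array_equal(
            self.predicted.residue_numbers, self.experimental.residue_numbers
        ):
            raise AlignmentError("profile pair has mismatched residue numbers")
        if len(self.predicted) < 3:
            raise ValueError("profile pair needs at least 3 shared residues")

    @property
    def n(self) -> int:
        return len(self.predicted)


def _pearson_xy(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc**2))
    sy = np.sqrt(np.sum(yc**2))
    if sx == 0.0 or sy == 0.0:
        raise UndefinedStatisticError("correlation undefined for a constant profile")
    return float(np.dot(xc, yc) / (sx * sy))


def pearson(pair: ProfilePair) -> float:
    """Pearson product-moment correlation of a profile pair."""
    return _pearson_xy(pair.predicted.values, pair.experimental.values)


def spearman(pair: ProfilePair) -> float:
    """Spearman rank correlation of a profile pair.

    Uses the rank-difference shortcut when all ranks are distinct and the
    Pearson correlation of average ranks otherwise (the tie-robust
    generalization, which coincides with the shortcut in the tie-free case).
    """
    x, y = pair.predicted.values, pair.experimental.values
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    n = pair.n
    no_ties = len(np.unique(x)) == n and len(np.unique(y)) == n
    if no_ties:
        d = rx - ry
        return float(1.0 - 6.0 * np.sum(d**2) / (n * (n**2 - 1)))
    return _pearson_xy(rx, ry)


def skewness(values) -> float:
    """Moment skewness g1 = m3 / m2^(3/2) with 1/n central moments."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("skewness needs at least 3 values")
    c = values - values.mean()
    m2 = np.mean(c**2)
    if m2 == 0.0:
        raise UndefinedStatisticError("skewness undefined for constant values")
    m3 = np.mean(c**3)
    return float(m3 / m2**1.5)


def histogram_counts(
    values, bin_width: float = 0.1, value_range: tuple[float, float] = (-1.0, 1.0)
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram counts over fixed-width bins.

    Bins are left-closed, right-open; the final bin is closed so that the
    upper range limit is counted.  Returns ``(edges, counts)`` with
    ``len(edges) == len(counts) + 1``; counts sum to ``len(values)``.
    """
    values = np.asarray(values, dtype=float)
    lo, hi = value_range
    if len(values) and (values.min() < lo or values.max() > hi):
        raise ValueError(f"values outside [{lo}, {hi}]")
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    return edges, counts


def cumulative_counts(values) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous counting function of a sample.

    Returns ``(x, count)`` where ``x`` is the sorted unique sample and
    ``count[k]`` is the number of values not exceeding ``x[k]``; the final
    count equals the sample size.
    """
    values = np.asarray(values, dtype=float)
    x = np.unique(values)
    srt = np.sort(values)
    counts = np.searchsorted(srt, x, side="right")
    return x, counts


def count_not_exceeding(values, x: float) -> int:
    """Number of sample values not exceeding ``x``."""
    values = np.sort(np.asarray(values, dtype=float))
    return int(np.searchsorted(values, x, side="right"))
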