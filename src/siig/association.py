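"""Correlation of the SIIG index with traits, and trait summaries.

Pearson product-moment correlations with two-sided p-values from the
exact t transform t = r * sqrt((n - 2) / (1 - r**2)) on n - 2 degrees
of freedom, marked with the field's conventional significance stars:
``*`` for p < 0.05 and ``**`` for p < 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import TraitMatrix

__all__ = [
    "Correlation",
    "CorrelationReport",
    "correlate",
    "correlation_matrix",
    "trait_summary",
    "column_difference",
    "stars_for_p",
]


def stars_for_p(p: float) -> str:
    """Two-tier significance code: '**' p<0.01, '*' p<0.05, '' otherwise."""
    if np.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class Correlation:
    r: float
    p: float
    n: int

    @property
    def stars(self) -> str:
        return stars_for_p(self.p)


@dataclass(frozen=True)
class CorrelationReport:
    """All pairwise correlations among a set of numeric columns.

    ``r``, ``p`` and ``stars`` are square DataFrames over the same
    variable axis; pairs involving a constant column are NaN / ''.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    n: int

    def long(self) -> pd.DataFrame:
        """Upper-triangle pairs as a long table (trait_a, trait_b, r, p, stars)."""
        cols = list(self.r.columns)
        rows = []
        for i, a in enumerate(cols):
            for b in cols[i + 1 :]:
                rows.append(
                    {
                        "trait_a": a,
                        "trait_b": b,
                        "r": self.r.loc[a, b],
                        "p": self.p.loc[a, b],
                        "stars": self.stars.loc[a, b],
                    }
                )
        return pd.DataFrame(rows)


def correlate(x: Sequence[float], y: Sequence[float]) -> Correlation:
    """Pearson r between two vectors with a two-sided t-test p-value."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError(f"length mismatch: {xa.shape[0]} vs {ya.shape[0]}")
    n = xa.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("zero variance input; correlation undefined")
    res = stats.pearsonr(xa, ya)
    return Correlation(r=float(res.statistic), p=float(res.pvalue), n=n)


def correlation_matrix(
    matrix: TraitMatrix | pd.DataFrame,
    siig: pd.Series | None = None,
    siig_name: str = "SIIG",
) -> CorrelationReport:
    """Pairwise Pearson correlations among traits, optionally with SIIG appended.

    Constant columns make their pairs undefined; those entries are NaN
    and the run continues with a warning.
    """
    df = matrix.data.copy() if isinstance(matrix, TraitMatrix) else matrix.copy()
    if siig is not None:
        df[siig_name] = siig.reindex(df.index).to_numpy()
    if df.shape[0] < 3:
        raise ValueError("need at least 3 genotypes")
    cols = list(df.columns)
    constant = [c for c in cols if np.ptp(df[c].to_numpy(dtype=float)) == 0]
    if constant:
        warnings.warn(
            f"constant column(s) {constant}: their correlations are undefined",
            stacklevel=2,
        )
    n = df.shape[0]
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            if a in constant or b in constant:
                rv, pv = np.nan, np.nan
            else:
                res = stats.pearsonr(df[a], df[b])
                rv, pv = float(res.statistic), float(res.pvalue)
            r.loc[a, b] = r.loc[b, a] = rv
            p.loc[a, b] = p.loc[b, a] = pv
    for c in constant:
        r.loc[c, c] = np.nan
        p.loc[c, c] = np.nan
    star = p.map(stars_for_p)
    for c in cols:
        star.loc[c, c] = ""
    return CorrelationReport(r=r, p=p, stars=star, n=n)


def trait_summary(matrix: TraitMatrix | pd.DataFrame) -> pd.DataFrame:
    """Per-trait mean, min and max (one row per trait)."""
    df = matrix.data if isinstance(matrix, TraitMatrix) else matrix
    if df.shape[0] == 0:
        raise ValueError("empty matrix")
    return pd.DataFrame(
        {"mean": df.mean(axis=0), "min": df.min(axis=0), "max": df.max(axis=0)}
    )


def column_difference(
    matrix: TraitMatrix | pd.DataFrame, col_a: str, col_b: str
) -> float:
    """Difference of column means, mean(col_a) - mean(col_b)."""
    df = matrix.data if isinstance(matrix, TraitMatrix) else matrix
    for c in (col_a, col_b):
        if c not in df.columns:
            raise KeyError(f"unknown column {c!r}; have {list(df.columns)}")
    return float(df[col_a].mean() - df[col_b].mean())
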