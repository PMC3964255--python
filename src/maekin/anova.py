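"""Balanced two-way ANOVA without replication, observed power, and the
Student-Newman-Keuls (SNK) multiple-comparison ranking.

The one-factor-at-a-time design yields a balanced factor x extraction-time
grid with one observation per cell (replicates averaged beforehand), so the
residual (interaction) mean square serves as the error term: for an
``a x b`` grid the effect degrees of freedom are ``a-1`` and ``b-1`` and the
error df is ``(a-1)(b-1)``.  With balanced data the Type III and Type I
sums of squares coincide, so the main-effect SS are plain row/column mean
contrasts.

Observed power follows the usual statistics-package convention: the
noncentrality is estimated as ``lambda = df_effect * F`` and the power is
the upper tail of the noncentral F beyond the central critical value at the
chosen alpha.

The SNK procedure ranks treatment means with studentized-range critical
values that shrink with the span of the compared means, applying the
standard step-down non-testing rule: a span inside an already-accepted
(homogeneous) span is never tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaRow",
    "AnovaTable",
    "SNKResult",
    "two_way_anova",
    "anova_from_ss",
    "observed_power",
    "snk_test",
]


@dataclass(frozen=True)
class AnovaRow:
    """One source line: sums of squares, df, mean square, F, p, noncentrality
    and observed power (the last four are None for error/total lines)."""

    source: str
    ss: float
    df: int
    ms: Optional[float] = None
    f: Optional[float] = None
    p: Optional[float] = None
    noncent: Optional[float] = None
    power: Optional[float] = None


@dataclass(frozen=True)
class AnovaTable:
    """Two-way ANOVA table in the balanced no-replication layout."""

    rows: tuple
    alpha: float
    zero_variance: bool = False

    def row(self, source: str) -> AnovaRow:
        for r in self.rows:
            if r.source == source:
                return r
        raise KeyError(source)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows]).set_index("source")

    def __str__(self) -> str:  # aligned text, SPSS-like column order
        df = self.to_frame()
        df.columns = ["Sum of squares", "df", "Mean square", "F", "Sig.",
                      "Noncent.", f"Obs. power (a={self.alpha})"]
        return df.to_string(float_format=lambda v: f"{v:.6g}")


def observed_power(noncent: float, df1: int, df2: int,
                   alpha: float = 0.05) -> float:
    """Power of the F test at noncentrality ``noncent``.

    ``P[F'(df1, df2, noncent) > F_crit(alpha, df1, df2)]``; equals ``alpha``
    when the noncentrality is zero and increases monotonically with it.
    """
    if noncent < 0:
        raise ValueError(f"noncentrality must be >= 0, got {noncent}")
    f_crit = stats.f.isf(alpha, df1, df2)
    if noncent == 0:
        return float(stats.f.sf(f_crit, df1, df2))
    return float(stats.ncf.sf(f_crit, df1, df2, noncent))


def _effect_row(source: str, ss: float, df: int, ms_err: float, df_err: int,
                alpha: float) -> AnovaRow:
    ms = ss / df
    if ms_err <= 0:
        return AnovaRow(source, ss, df, ms, math.nan, math.nan, math.nan,
                        math.nan)
    f_ratio = ms / ms_err
    p = float(stats.f.sf(f_ratio, df, df_err))
    lam = df * f_ratio
    return AnovaRow(source, ss, df, ms, f_ratio, p, lam,
                    observed_power(lam, df, df_err, alpha))


def anova_from_ss(ss_a: float, df_a: int, ss_b: float, df_b: int,
                  ss_err: float, df_err: int, alpha: float = 0.05,
                  labels: Sequence[str] = ("factor", "time")) -> AnovaTable:
    """Build the full ANOVA table from known sums of squares and df.

    This is the entry point for reproducing published tables whose raw data
    are unavailable: mean squares, F ratios, p values, noncentralities
    (``df * F``) and observed powers are filled in from the SS/df pairs.
    """
    for name, ss, df in (("A", ss_a, df_a), ("B", ss_b, df_b),
                         ("error", ss_err, df_err)):
        if ss < 0:
            raise ValueError(f"ss_{name} must be >= 0")
        if df < 1:
            raise ValueError(f"df_{name} must be >= 1 (df_err = 0 included)")
    ms_err = ss_err / df_err
    rows = (
        _effect_row(labels[0], ss_a, df_a, ms_err, df_err, alpha),
        _effect_row(labels[1], ss_b, df_b, ms_err, df_err, alpha),
        AnovaRow("error", ss_err, df_err, ms_err),
        AnovaRow("total", ss_a + ss_b + ss_err, df_a + df_b + df_err),
    )
    return AnovaTable(rows=rows, alpha=alpha, zero_variance=(ms_err == 0))


def two_way_anova(data, alpha: float = 0.05,
                  labels: Optional[Sequence[str]] = None) -> AnovaTable:
    """Balanced two-way ANOVA with one observation per cell.

    Parameters
    ----------
    data : OFATDataset or ndarray of shape (a, b)
        Factor levels on the rows, extraction times on the columns; a
        ragged or otherwise unbalanced input is rejected outright.
    alpha : float
        Significance level for the observed-power column.
    labels : (row_label, col_label) or None

    Returns
    -------
    AnovaTable
        Main effects tested against the residual (interaction) mean square;
        a grid with no variance at all comes back flagged with NaN F ratios.
    """
    if hasattr(data, "yields"):
        grid = np.asarray(data.yields, dtype=float)
        labels = labels or (data.factor_name, "time")
    else:
        if isinstance(data, (list, tuple)) and any(
                len(row) != len(data[0]) for row in data):
            raise ValueError("unbalanced grid: every level needs every time")
        grid = np.asarray(data, dtype=float)
        labels = labels or ("factor", "time")
    if grid.ndim != 2:
        raise ValueError("grid must be 2-D (levels x times)")
    a, b = grid.shape
    if a < 2 or b < 2:
        raise ValueError("need >= 2 levels of each factor")
    if not np.all(np.isfinite(grid)):
        raise ValueError("unbalanced grid: missing cells are not supported")

    grand = grid.mean()
    ss_a = b * float(np.sum((grid.mean(axis=1) - grand) ** 2))
    ss_b = a * float(np.sum((grid.mean(axis=0) - grand) ** 2))
    ss_tot = float(np.sum((grid - grand) ** 2))
    ss_err = max(ss_tot - ss_a - ss_b, 0.0)
    return anova_from_ss(ss_a, a - 1, ss_b, b - 1, ss_err,
                         (a - 1) * (b - 1), alpha=alpha, labels=labels)


@lru_cache(maxsize=4096)
def _q_crit(alpha: float, r: int, df: float) -> float:
    """Cached studentized-range upper quantile (scipy's is expensive)."""
    return float(stats.studentized_range.isf(alpha, r, df))


@dataclass(frozen=True)
class SNKResult:
    """Outcome of the Student-Newman-Keuls ranking.

    ``means``/``labels`` are ordered descending; ``subsets`` are groups of
    labels whose means are not significantly different (contiguous in the
    ordering); ``critical_ranges`` maps span size to the critical difference
    used for that span.
    """

    means: np.ndarray
    labels: tuple
    subsets: tuple
    critical_ranges: dict
    alpha: float

    def top_subset(self) -> tuple:
        return self.subsets[0]


def snk_test(means: Sequence[float], n_per_mean: int, ms_error: float,
             df_error: int, alpha: float = 0.05,
             labels: Optional[Sequence] = None) -> SNKResult:
    """Student-Newman-Keuls step-down ranking of treatment means.

    Means are sorted descending and spans of size ``r`` are compared against
    ``q(alpha, r, df_error) * sqrt(ms_error / n)``.  Non-significant spans
    become homogeneous subsets and, by the step-down non-testing rule, their
    sub-spans are never tested.  A zero error mean square degenerates to
    grouping exactly equal means.

    Parameters
    ----------
    means : per-level means, mg/g
    n_per_mean : observations behind each mean
    ms_error : error mean square from the ANOVA
    df_error : its degrees of freedom
    alpha : significance level
    labels : level labels; defaults to the mean values' indices
    """
    means = np.asarray(means, dtype=float)
    k = len(means)
    if k < 2:
        raise ValueError("need >= 2 means to rank")
    if ms_error < 0:
        raise ValueError("ms_error must be >= 0")
    if labels is None:
        labels = tuple(range(k))
    labels = tuple(labels)
    if len(labels) != k:
        raise ValueError("labels length must match means")

    order = np.argsort(-means, kind="stable")
    m = means[order]
    lab = tuple(labels[i] for i in order)

    if ms_error == 0:
        subsets, start = [], 0
        for i in range(1, k + 1):
            if i == k or m[i] != m[start]:
                subsets.append(lab[start:i])
                start = i
        return SNKResult(m, lab, tuple(subsets), {}, alpha)

    se = math.sqrt(ms_error / n_per_mean)
    critical = {r: _q_crit(alpha, r, df_error) * se
                for r in range(2, k + 1)}

    accepted: list[tuple[int, int]] = []
    pending = {(0, k - 1)}
    for size in range(k, 1, -1):
        nxt: set[tuple[int, int]] = set()
        for i, j in sorted(pending):
            if any(ai <= i and j <= aj for ai, aj in accepted):
                continue  # step-down non-testing rule
            if m[i] - m[j] > critical[j - i + 1]:
                if j - i >= 2:
                    nxt.add((i, j - 1))
                    nxt.add((i + 1, j))
            else:
                accepted.append((i, j))
        pending = nxt

    covered = set()
    for ai, aj in accepted:
        covered.update(range(ai, aj + 1))
    spans = sorted(accepted) + [(i, i) for i in range(k) if i not in covered]
    subsets = tuple(lab[i:j + 1] for i, j in sorted(spans))
    return SNKResult(m, lab, subsets, critical, alpha)
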