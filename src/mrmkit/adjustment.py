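"""Urinary-concentration adjustment and residual-correlation diagnostics.

Urinary protein concentrations confound the signal of interest with
diuresis (urine dilution), tubular reabsorption of low-molecular-weight
proteins, and glomerular leakage.  Two adjustment strategies are compared on
log-transformed concentrations:

* division      — ``adjusted = log A - log X`` (the classic per-gram-of-
  creatinine ratio, expressed on the log scale);
* regression    — ``adjusted_i = log A_i - beta (log X_i - mean(log X))``
  where beta is the OLS slope of log A on log X.  By the normal-equation
  orthogonality of least squares the adjusted series is exactly
  uncorrelated with the adjuster (r = 0.00), while division generally
  over- or under-corrects and leaves residual correlations.

The residual table machinery reproduces that comparison for any cohort:
a full Pearson matrix over the unadjusted analytes, the adjusters, and each
analyte-by-adjuster adjusted series, with two-tailed t-test p-values and the
significance tiers $ (p<0.05), # (p<0.01), * (p<0.001).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PearsonResult",
    "AdjustmentResult",
    "CorrelationReport",
    "log_transform",
    "pearson",
    "significance_stars",
    "adjust_division",
    "adjust_regression",
    "residual_table",
]


def log_transform(matrix: pd.DataFrame, base: float = 10.0) -> Tuple[pd.DataFrame, pd.Series]:
    """Element-wise logarithm of a samples x analytes table.

    Non-positive or missing values are masked to NaN (handled pairwise
    downstream) and counted per column, never silently dropped.  Returns
    (log matrix, per-column masked counts).
    """
    values = matrix.astype(float)
    invalid = ~(values > 0)  # catches NaN as well
    masked_counts = invalid.sum()
    logged = np.log(values.where(~invalid)) / np.log(base)
    return logged, masked_counts


class PearsonResult(NamedTuple):
    r: float
    p: float
    n: int


def pearson(x, y) -> PearsonResult:
    """Pearson r with a two-tailed t-test p-value over complete pairs.

    p derives from t = r sqrt((n-2)/(1-r²)) on n-2 degrees of freedom, which
    is what :func:`scipy.stats.pearsonr` computes.
    """
    x = pd.Series(np.asarray(x, dtype=float)) if not isinstance(x, pd.Series) else x
    y = pd.Series(np.asarray(y, dtype=float)) if not isinstance(y, pd.Series) else y
    x, y = x.align(y, join="inner")
    mask = x.notna() & y.notna()
    xv, yv = x[mask].to_numpy(), y[mask].to_numpy()
    n = len(xv)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.allclose(xv, xv[0]):
        raise ValueError("first column has zero variance")
    if np.allclose(yv, yv[0]):
        raise ValueError("second column has zero variance")
    r, p = stats.pearsonr(xv, yv)
    return PearsonResult(float(r), float(p), n)


def significance_stars(p: float) -> str:
    """$ p<0.05, # p<0.01, * p<0.001."""
    if p < 0.001:
        return "*"
    if p < 0.01:
        return "#"
    if p < 0.05:
        return "$"
    return ""


def adjust_division(log_analyte: pd.Series, log_adjuster: pd.Series) -> pd.Series:
    """Log-scale ratio adjustment: log analyte minus log adjuster."""
    a, x = log_analyte.align(log_adjuster, join="inner")
    return a - x


@dataclass
class AdjustmentResult:
    analyte: str
    adjuster: str
    method: str  # 'division' | 'regression'
    adjusted: pd.Series
    beta: Optional[float] = None


def adjust_regression(
    log_analyte: pd.Series,
    log_adjuster: pd.Series,
    analyte: str = "analyte",
    adjuster: str = "adjuster",
) -> AdjustmentResult:
    """Regression-coefficient adjustment.

    beta is the OLS slope of log analyte on log adjuster over complete pairs;
    the adjusted series is the regression residual re-centred on the analyte
    mean, so it keeps the analyte's log scale and is exactly orthogonal to
    the adjuster.
    """
    a, x = log_analyte.align(log_adjuster, join="inner")
    mask = a.notna() & x.notna()
    if mask.sum() < 3:
        raise ValueError("need at least 3 complete pairs")
    xv = x[mask].to_numpy()
    if np.allclose(xv, xv[0]):
        raise ValueError("adjuster has zero variance")
    fit = stats.linregress(xv, a[mask].to_numpy())
    beta = float(fit.slope)
    adjusted = a - beta * (x - float(np.mean(xv)))
    return AdjustmentResult(
        analyte=analyte, adjuster=adjuster, method="regression",
        adjusted=adjusted, beta=beta,
    )


@dataclass
class CorrelationReport:
    """Pairwise-complete Pearson matrices with significance stars."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    stars: pd.DataFrame
    notes: List[str] = field(default_factory=list)

    def formatted(self) -> pd.DataFrame:
        """r rounded to 2 decimals with the significance tier appended."""
        out = self.r.round(2).astype(str) + self.stars
        return out

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        cols = list(self.r.columns)
        for i, a in enumerate(cols):
            for b in cols[i:]:
                rows.append(
                    {
                        "var_a": a,
                        "var_b": b,
                        "r": self.r.loc[a, b],
                        "p": self.p.loc[a, b],
                        "n": self.n.loc[a, b],
                        "stars": self.stars.loc[a, b],
                    }
                )
        return pd.DataFrame(rows)


def correlation_report(frame: pd.DataFrame) -> CorrelationReport:
    """Full pairwise-complete Pearson matrix over the frame's columns."""
    cols = list(frame.columns)
    k = len(cols)
    r = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    p = r.copy()
    n = pd.DataFrame(np.zeros((k, k), dtype=int), index=cols, columns=cols)
    notes: List[str] = []
    for i, a in enumerate(cols):
        mask_a = frame[a].notna()
        r.loc[a, a], p.loc[a, a], n.loc[a, a] = 1.0, 0.0, int(mask_a.sum())
        for b in cols[i + 1 :]:
            try:
                res = pearson(frame[a], frame[b])
            except ValueError as exc:
                notes.append(f"{a} vs {b}: {exc}")
                continue
            r.loc[a, b] = r.loc[b, a] = res.r
            p.loc[a, b] = p.loc[b, a] = res.p
            n.loc[a, b] = n.loc[b, a] = res.n
    stars = p.map(lambda v: significance_stars(v) if v == v and v > 0 else "*")
    stars = stars.where(r.notna(), "")
    for c in cols:
        stars.loc[c, c] = "*"  # diagonal r = 1 is trivially significant
    return CorrelationReport(r=r, p=p, n=n, stars=stars, notes=notes)


def residual_table(
    cohort_log: pd.DataFrame,
    analytes: Sequence[str] = ("CC16", "OPN"),
    adjusters: Sequence[str] = ("RBP4", "B2M", "CREAT", "HSA"),
    method: str = "division",
) -> CorrelationReport:
    """Residual-correlation diagnostics for one adjustment method.

    Builds, from a log-transformed cohort, the unadjusted analyte and
    adjuster columns plus one ``{analyte}-{adjuster}`` column per pair
    (division or regression adjusted) and returns the full correlation
    report.  For the regression method every ``(analyte-X, X)`` entry is
    0.00 by construction.  Entirely missing or constant columns are noted
    and the remaining table is still produced.
    """
    if method not in ("division", "regression"):
        raise ValueError("method must be 'division' or 'regression'")
    frame = pd.DataFrame(index=cohort_log.index)
    notes: List[str] = []
    for col in list(analytes) + [a for a in adjusters if a not in analytes]:
        if col not in cohort_log.columns:
            notes.append(f"column {col!r} absent from cohort")
            continue
        if cohort_log[col].notna().sum() == 0:
            notes.append(f"column {col!r} entirely missing")
            continue
        frame[col] = cohort_log[col]
    for analyte in analytes:
        if analyte not in frame.columns:
            continue
        for adj in adjusters:
            if adj not in frame.columns or adj == analyte:
                continue
            name = f"{analyte}-{adj}"
            if method == "division":
                adjusted = adjust_division(frame[analyte], frame[adj])
                if adjusted.dropna().nunique() <= 1:
                    notes.append(f"{name}: adjusted series has zero variance")
                    continue
            else:
                try:
                    adjusted = adjust_regression(
                        frame[analyte], frame[adj], analyte, adj
                    ).adjusted
                except ValueError as exc:
                    notes.append(f"{name}: {exc}")
                    continue
            frame[name] = adjusted
    report = correlation_report(frame)
    report.notes = notes + report.notes
    return report
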