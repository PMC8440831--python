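"""Test-retest and inter-operator reliability statistics.

ICC(2,1) -- the single-measure, absolute-agreement intraclass correlation
from a two-way random-effects ANOVA -- with its 95% confidence interval
(McGraw & Wong formulation) and F-test p-value, the standard error of
measurement SEM = SD * sqrt(1 - ICC), the smallest detectable difference
SDD = SEM * 1.96 * sqrt(2), and the conventional classification of ICC
values as poor (< 0.40), fair to good (0.40-0.75) or excellent (> 0.75).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ICC_POOR_BELOW = 0.40
ICC_EXCELLENT_ABOVE = 0.75


class DegenerateTableError(ValueError):
    """No between-subject variance and no error variance: ICC undefined."""


@dataclass
class ReliabilityResult:
    parameter: str
    units: str
    icc: float
    ci_low: float
    ci_high: float
    p_value: float
    sd: float
    sem: float
    sdd: float
    label: str
    mean_rom: float
    min_rom: float
    max_rom: float

    def to_series(self) -> pd.Series:
        return pd.Series({
            "parameter": self.parameter, "units": self.units,
            "ICC": self.icc, "CI95_low": self.ci_low,
            "CI95_high": self.ci_high, "p": self.p_value, "SD": self.sd,
            "SEM": self.sem, "SDD": self.sdd, "classification": self.label,
            "mean_ROM": self.mean_rom, "min_ROM": self.min_rom,
            "max_ROM": self.max_rom})


def _as_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need a (subjects x raters) table, >= 2 each")
    if not np.isfinite(t).all():
        raise ValueError("table has missing cells")
    return t


def anova_mean_squares(table):
    """Two-way ANOVA mean squares (rows, columns, error) of a full table."""
    t = _as_table(table)
    n, k = t.shape
    grand = t.mean()
    row_means = t.mean(axis=1)
    col_means = t.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((t - grand) ** 2)
    sse = max(sst - ssr - ssc, 0.0)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_2_1(table, alpha: float = 0.05):
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Returns (icc, (ci_low, ci_high), p_value). The p-value tests H0: ICC = 0
    via F = MSR / MSE on (n-1, (n-1)(k-1)) degrees of freedom (the standard
    output convention); the CI follows McGraw & Wong with a Satterthwaite
    approximation for the denominator degrees of freedom.
    """
    t = _as_table(table)
    n, k = t.shape
    msr, msc, mse = anova_mean_squares(t)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or (msr == 0 and mse == 0 and msc == 0):
        raise DegenerateTableError(
            "zero between-subject and error variance: ICC undefined")
    icc = (msr - mse) / denom

    df1, df2 = n - 1, (n - 1) * (k - 1)
    if mse == 0:
        p = 0.0
        return float(icc), (float(icc), float(icc)), p
    fvalue = msr / mse
    p = float(sps.f.sf(fvalue, df1, df2))

    # McGraw & Wong confidence bounds for ICC(A,1)
    if icc >= 1.0:
        return float(icc), (1.0, 1.0), p
    a = (k * icc) / (n * (1.0 - icc))
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
    f_l = sps.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_u = sps.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    lo = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return float(icc), (float(lo), float(hi)), p


def sem(sd: float, icc: float) -> float:
    """Standard error of measurement: SD * sqrt(1 - ICC)."""
    if icc > 1.0:
        raise ValueError("ICC cannot exceed 1")
    if sd < 0:
        raise ValueError("SD must be nonnegative")
    return float(sd * math.sqrt(1.0 - icc))


def sdd(sem_value: float) -> float:
    """Smallest detectable difference: SEM * 1.96 * sqrt(2)."""
    if sem_value < 0:
        raise ValueError("SEM must be nonnegative")
    return float(sem_value * 1.96 * math.sqrt(2.0))


def classify_icc(icc: float) -> str:
    """poor (< 0.40), fair to good (0.40-0.75, closed), excellent (> 0.75)."""
    if icc > 1.0:
        raise ValueError("ICC cannot exceed 1")
    if icc < ICC_POOR_BELOW:
        return "poor"
    if icc <= ICC_EXCELLENT_ABOVE:
        return "fair to good"
    return "excellent"


def sd_between_columns(table, method: str = None) -> float:
    """The SD entering the SEM formula.

    ``abs_diff`` (two columns): SD of the per-subject absolute
    between-column differences -- the reading of the test-retest table
    legend. ``relative_to_mean`` (any k): mean over subjects of the SD of
    each subject's values about their own mean -- the reading of the
    inter-operator table legend. Default: abs_diff when k == 2, else
    relative_to_mean.
    """
    t = _as_table(table)
    n, k = t.shape
    if method is None:
        method = "abs_diff" if k == 2 else "relative_to_mean"
    if method == "abs_diff":
        if k != 2:
            raise ValueError("abs_diff needs exactly 2 columns")
        return float(np.std(np.abs(t[:, 0] - t[:, 1]), ddof=1))
    if method == "relative_to_mean":
        return float(np.mean(np.std(t, axis=1, ddof=1)))
    raise ValueError(f"unknown SD method {method!r}")


def analyze_reliability(table, parameter: str = "", units: str = "deg",
                        sd_method: str = None) -> ReliabilityResult:
    """Full reliability summary of one subjects-by-sessions ROM table."""
    t = _as_table(table)
    icc, (lo, hi), p = icc_2_1(t)
    sd_val = sd_between_columns(t, method=sd_method)
    sem_val = sem(sd_val, min(icc, 1.0))
    return ReliabilityResult(
        parameter=parameter, units=units, icc=icc, ci_low=lo, ci_high=hi,
        p_value=p, sd=sd_val, sem=sem_val, sdd=sdd(sem_val),
        label=classify_icc(icc), mean_rom=float(t.mean()),
        min_rom=float(t.mean(axis=1).min()), max_rom=float(t.mean(axis=1).max()))


def reliability_table(long_df: pd.DataFrame, sd_method: str = None) -> pd.DataFrame:
    """Reliability per parameter from a long table.

    ``long_df`` columns: parameter, subject, rater, value (and optionally
    units). Each parameter must form a complete subjects-by-raters grid.
    """
    rows = []
    for param, grp in long_df.groupby("parameter", sort=False):
        wide = grp.pivot(index="subject", columns="rater", values="value")
        if wide.isna().any().any():
            raise ValueError(f"parameter {param!r} has missing cells")
        units = (grp["units"].iloc[0] if "units" in grp else
                 ("cm" if param.upper() == "SVA" else "deg"))
        rows.append(analyze_reliability(wide.to_numpy(), parameter=param,
                                        units=units,
                                        sd_method=sd_method).to_series())
    return pd.DataFrame(rows)
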