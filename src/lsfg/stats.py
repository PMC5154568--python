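"""Study statistics: hemodynamics, repeatability, association, comparisons.

Implements the statistical battery of a test–retest flowgraphy study:

* derived hemodynamics — MAP = DBP + (SBP − DBP)/3, PPA = SBP − DBP,
  OPP = (2/3)·MAP − IOP;
* coefficient of variation — mean within-subject SD of repeated scans over
  the grand mean, in percent;
* intraclass correlation — from repeated-measures ANOVA mean squares,
  default two-way mixed, consistency, single measurement
  (ICC(3,1) = (MS_subjects − MS_error)/(MS_subjects + (k−1)·MS_error));
* Pearson association with a regression line and 95% confidence band;
* paired and independent t-tests; 2×2 chi-square for scan success rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .config import StatsConfig

__all__ = [
    "SystemicHemodynamics",
    "RepeatabilityResult",
    "AssociationResult",
    "ComparisonResult",
    "SuccessRateResult",
    "derived_hemodynamics",
    "coefficient_of_variation",
    "intraclass_correlation",
    "association",
    "paired_comparison",
    "group_comparison",
    "success_rate_test",
]


@dataclass
class SystemicHemodynamics:
    """Blood-pressure-derived perfusion quantities (all mmHg)."""

    sbp: float
    dbp: float
    iop: float
    map: float
    ppa: float
    opp: float


@dataclass
class RepeatabilityResult:
    index_name: str
    cov: float  # percent
    icc: float
    n_subjects: int
    n_repeats: int


@dataclass
class AssociationResult:
    """Pearson correlation with the fitted regression line and CI band.

    The 95% pointwise confidence band for the mean response at x is
    ``yhat(x) ± t_crit · s · sqrt(1/n + (x − x_mean)² / sxx)``.
    """

    r: float
    p: float
    slope: float
    intercept: float
    n: int
    x_mean: float
    sxx: float
    resid_sd: float
    t_crit: float

    def ci_band(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, dtype=float)
        yhat = self.intercept + self.slope * x
        half = self.t_crit * self.resid_sd * np.sqrt(
            1.0 / self.n + (x - self.x_mean) ** 2 / self.sxx)
        return yhat - half, yhat + half


@dataclass
class ComparisonResult:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    mean_difference: float


@dataclass
class SuccessRateResult:
    rate_a: float  # percent, rounded to one decimal
    rate_b: float
    chi2: float
    p: float
    warning: str | None = None


# ---------------------------------------------------------------------------


def derived_hemodynamics(
    sbp: float, dbp: float, iop: float, formula: str = "standard"
) -> SystemicHemodynamics:
    """Mean arterial pressure, pulse pressure amplitude, ocular perfusion pressure.

    ``formula='standard'`` uses MAP = DBP + (SBP − DBP)/3; ``'printed'``
    uses MAP = SBP + (SBP − DBP)/3 (kept only for fidelity comparisons —
    it is inconsistent with typical study summary tables).
    """
    if not sbp > dbp > 0:
        raise ValueError("need sbp > dbp > 0")
    if iop < 0:
        raise ValueError("iop must be >= 0")
    if formula == "standard":
        mean_ap = dbp + (sbp - dbp) / 3.0
    elif formula == "printed":
        mean_ap = sbp + (sbp - dbp) / 3.0
    else:
        raise ValueError("formula must be 'standard' or 'printed'")
    ppa = sbp - dbp
    opp = (2.0 / 3.0) * mean_ap - iop
    return SystemicHemodynamics(sbp=sbp, dbp=dbp, iop=iop,
                                map=mean_ap, ppa=ppa, opp=opp)


def _as_matrix(measurements: np.ndarray) -> np.ndarray:
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a (subjects × repeats) matrix, both >= 2")
    if np.isnan(m).any():
        raise ValueError("matrix contains missing values; drop incomplete subjects")
    return m


def coefficient_of_variation(measurements: np.ndarray) -> float:
    """COV (%) = 100 · mean over subjects of within-subject SD / grand mean.

    Within-subject SD uses the n−1 denominator.  Scale-invariant.
    """
    m = _as_matrix(measurements)
    grand = m.mean()
    if grand <= 0:
        raise ValueError("COV undefined for non-positive grand mean")
    return float(100.0 * m.std(axis=1, ddof=1).mean() / grand)


def anova_mean_squares(m: np.ndarray) -> tuple[float, float, float]:
    """Two-way repeated-measures ANOVA mean squares (subjects, repeats, error)."""
    n, k = m.shape
    grand = m.mean()
    ss_subj = k * float(((m.mean(axis=1) - grand) ** 2).sum())
    ss_rep = n * float(((m.mean(axis=0) - grand) ** 2).sum())
    ss_tot = float(((m - grand) ** 2).sum())
    ss_err = ss_tot - ss_subj - ss_rep
    ms_subj = ss_subj / (n - 1)
    ms_rep = ss_rep / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return ms_subj, ms_rep, ms_err


def intraclass_correlation(
    measurements: np.ndarray,
    form: str = "icc3",
    index_name: str = "",
) -> RepeatabilityResult:
    """ICC of a subjects × repeats matrix from ANOVA mean squares.

    ``icc3``  two-way mixed, consistency, single measurement (default);
    ``icc2``  two-way random, absolute agreement, single measurement;
    ``oneway`` one-way random, single measurement.
    """
    m = _as_matrix(measurements)
    n, k = m.shape
    ms_subj, ms_rep, ms_err = anova_mean_squares(m)
    if form == "icc3":
        denom = ms_subj + (k - 1) * ms_err
        icc = (ms_subj - ms_err) / denom if denom > 0 else 1.0
    elif form == "icc2":
        denom = ms_subj + (k - 1) * ms_err + k * (ms_rep - ms_err) / n
        icc = (ms_subj - ms_err) / denom if denom > 0 else 1.0
    elif form == "oneway":
        ss_within = float(((m - m.mean(axis=1, keepdims=True)) ** 2).sum())
        ms_within = ss_within / (n * (k - 1))
        denom = ms_subj + (k - 1) * ms_within
        icc = (ms_subj - ms_within) / denom if denom > 0 else 1.0
    else:
        raise ValueError("form must be one of icc3, icc2, oneway")
    cov = coefficient_of_variation(m) if m.mean() > 0 else float("nan")
    return RepeatabilityResult(index_name=index_name, cov=cov, icc=float(icc),
                               n_subjects=n, n_repeats=k)


def association(x: np.ndarray, y: np.ndarray) -> AssociationResult:
    """Pearson correlation and least-squares line with a 95% CI band."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("association undefined for zero-variance input")
    n = x.size
    r, p = sps.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    resid_sd = float(np.sqrt((resid ** 2).sum() / (n - 2))) if n > 2 else 0.0
    sxx = float(((x - x.mean()) ** 2).sum())
    t_crit = float(sps.t.ppf(0.975, n - 2))
    return AssociationResult(r=float(r), p=float(p), slope=float(slope),
                             intercept=float(intercept), n=n,
                             x_mean=float(x.mean()), sxx=sxx,
                             resid_sd=resid_sd, t_crit=t_crit)


def paired_comparison(before: np.ndarray, after: np.ndarray) -> ComparisonResult:
    """Two-sided paired t-test; degenerate zero-variance cases handled explicitly."""
    a = np.asarray(before, dtype=float)
    b = np.asarray(after, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need n >= 2 pairs")
    d = b - a
    n = d.size
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):  # identical samples
            return ComparisonResult(t=0.0, df=n - 1, p=1.0,
                                    mean_a=float(a.mean()), mean_b=float(b.mean()),
                                    mean_difference=0.0)
        # constant non-zero shift: certainty in the limit
        return ComparisonResult(t=float("inf"), df=n - 1, p=0.0,
                                mean_a=float(a.mean()), mean_b=float(b.mean()),
                                mean_difference=float(d.mean()))
    t, p = sps.ttest_rel(b, a)
    return ComparisonResult(t=float(t), df=n - 1, p=float(p),
                            mean_a=float(a.mean()), mean_b=float(b.mean()),
                            mean_difference=float(d.mean()))


def group_comparison(
    group_a: np.ndarray, group_b: np.ndarray, welch: bool = False
) -> ComparisonResult:
    """Two-sided independent-samples t-test (pooled variance by default)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    if welch:
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        df = (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))
    else:
        df = a.size + b.size - 2
    return ComparisonResult(t=float(t), df=float(df), p=float(p),
                            mean_a=float(a.mean()), mean_b=float(b.mean()),
                            mean_difference=float(a.mean() - b.mean()))


def success_rate_test(
    success_a: int, total_a: int, success_b: int, total_b: int,
    yates: bool = False,
) -> SuccessRateResult:
    """Pearson chi-square on the 2×2 success table, 1 df, two-sided.

    No continuity correction by default.  Rates are returned as percentages
    rounded to one decimal.  If any expected cell count is below 1 a warning
    is attached but the result is still returned.
    """
    for s, t in ((success_a, total_a), (success_b, total_b)):
        if t <= 0:
            raise ValueError("totals must be positive")
        if not 0 <= s <= t:
            raise ValueError("successes must lie in [0, total]")
    table = np.array([[success_a, total_a - success_a],
                      [success_b, total_b - success_b]], dtype=float)
    warning = None
    if table.sum() > 0:
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        if (expected < 1).any():
            warning = "expected cell count below 1; chi-square unreliable"
            warnings.warn(warning, stacklevel=2)
    if np.any(table.sum(axis=0) == 0):
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = sps.chi2_contingency(table, correction=yates)
    return SuccessRateResult(
        rate_a=round(100.0 * success_a / total_a, 1),
        rate_b=round(100.0 * success_b / total_b, 1),
        chi2=float(chi2), p=float(p), warning=warning)
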