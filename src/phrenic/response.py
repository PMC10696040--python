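"""Percent-of-baseline drug responses, change rates and group statistics.

Normalisation follows the convention that the mean of a metric over the
100 s preceding the injection defines 100 %.  The change rate of a metric is
its mean percent value over a post-injection analysis window (the shaded
region of a response time-course plot).  Group inference uses a one-sample
t-test against 100 %, a paired t-test between protocols, or a one-way
repeated-measures ANOVA across timepoints followed by Dunnett many-to-one
comparisons against the pre-injection control timepoint.  All tests are
two-sided; significance is declared at p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy import stats as sstats

from .types import GroupStats, MetricTimeCourse

__all__ = [
    "percent_of_baseline", "change_rate", "one_sample_t", "paired_t",
    "rm_anova_dunnett", "dunnett_critical_value", "RMANOVAResult",
]

log = logging.getLogger(__name__)


def percent_of_baseline(tc: MetricTimeCourse, injection_time: float,
                        baseline_dur: float = 100.0) -> MetricTimeCourse:
    """Normalise a time course so the pre-injection baseline mean is 100 %.

    The baseline window is ``[injection - baseline_dur, injection)``.  Gaps
    (NaN) propagate unchanged.
    """
    if baseline_dur <= 0:
        raise ValueError("baseline_dur must be positive")
    m = (tc.times >= injection_time - baseline_dur) & (tc.times < injection_time)
    base_vals = tc.values[m]
    base_vals = base_vals[np.isfinite(base_vals)]
    if base_vals.size == 0:
        raise ValueError("no samples in the baseline window")
    base = float(base_vals.mean())
    if base == 0:
        raise ValueError("baseline mean is zero; cannot normalise")
    percent = 100.0 * tc.values / base
    return MetricTimeCourse(tc.metric, tc.times.copy(), tc.values.copy(), percent)


def change_rate(tc: MetricTimeCourse, window: tuple[float, float],
                injection_time: float = 0.0) -> float:
    """Mean percent value over the analysis window.

    ``window`` is relative to the injection, e.g. ``(60, 180)`` brackets the
    period around the peak drug effect.
    """
    if tc.percent is None:
        raise ValueError("time course is not normalised; run percent_of_baseline first")
    lo, hi = injection_time + window[0], injection_time + window[1]
    m = (tc.times >= lo) & (tc.times < hi)
    vals = tc.percent[m]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no samples in the analysis window")
    return float(vals.mean())


def one_sample_t(values, mu0: float = 100.0, metric: str = "") -> GroupStats:
    """Two-sided one-sample t-test against ``mu0`` (classical closed form)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values")
    n = x.size
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    sem = sd / np.sqrt(n)
    df = n - 1
    if sd == 0.0:
        if mean == mu0:
            return GroupStats(metric, n, mean, 0.0, "one-sample t", 0.0, 1.0, df)
        t = np.inf if mean > mu0 else -np.inf
        return GroupStats(metric, n, mean, 0.0, "one-sample t", t, 0.0, df,
                          degenerate=True)
    t = (mean - mu0) / sem
    p = 2.0 * sstats.t.sf(abs(t), df)
    return GroupStats(metric, n, mean, sem, "one-sample t", float(t), float(p), df)


def paired_t(before, after, metric: str = "") -> GroupStats:
    """Two-sided paired t-test: one-sample t on (after - before) against 0.

    The reported mean/SEM summarise the pairwise differences.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape:
        raise ValueError("before/after length mismatch")
    gs = one_sample_t(a - b, mu0=0.0, metric=metric)
    gs.test = "paired t"
    return gs


@dataclass
class RMANOVAResult:
    """One-way repeated-measures ANOVA plus Dunnett many-to-one comparisons."""

    F: float
    df_time: float
    df_error: float
    pvalue: float
    ms_error: float
    n_subjects: int
    control_index: int
    timepoints: list[GroupStats]
    n_dropped: int = 0

    @property
    def any_significant(self) -> bool:
        return any(g.significant for g in self.timepoints)

    @property
    def max_abs_t(self) -> float:
        return max((abs(g.statistic) for g in self.timepoints), default=0.0)


# quadrature grids for the Dunnett equicoordinate probability
_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(80)
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(80)


def _dunnett_prob(c: float, m: int, df: float) -> float:
    """P(max_i |T_i| <= c) for m equicorrelated (rho = 1/2) t contrasts.

    Uses the factor representation T_i = (Z_i + Z_0) / (sqrt(2) * W) with
    W^2 = chi2_df / df, reducing the m-variate probability to a 2-D
    quadrature: Gauss-Hermite over the shared factor Z_0 and Gauss-Legendre
    over the chi-square quantile of W.  Deterministic, ~1e-6 accurate.
    """
    if c <= 0:
        return 0.0
    # z integral: Z_0 ~ N(0,1) via Hermite nodes (z = sqrt(2) x)
    z = np.sqrt(2.0) * _GH_NODES
    wz = _GH_WEIGHTS / np.sqrt(np.pi)
    # w integral: substitute u = F_chi2(df * w^2), u on (0,1)
    u = 0.5 * (_GL_NODES + 1.0)
    wu = 0.5 * _GL_WEIGHTS
    w = np.sqrt(sstats.chi2.ppf(u, df) / df)
    a = c * np.sqrt(2.0) * w  # (nu,)
    inner = sstats.norm.cdf(a[:, None] - z[None, :]) - sstats.norm.cdf(
        -a[:, None] - z[None, :])
    vals = np.clip(inner, 0.0, 1.0) ** m
    prob = float(wu @ (vals @ wz))
    return float(np.clip(prob, 0.0, 1.0))


def dunnett_critical_value(m: int, df: float, alpha: float = 0.05) -> float:
    """Two-sided Dunnett critical value for m comparisons against one control."""
    if m == 1:
        return float(sstats.t.ppf(1 - alpha / 2, df))
    f = lambda c: _dunnett_prob(c, m, df) - (1 - alpha)
    lo = sstats.t.ppf(1 - alpha / 2, df) * 0.9
    return float(optimize.brentq(f, lo, 20.0, xtol=1e-6))


def rm_anova_dunnett(matrix, control_index: int = 0,
                     metric: str = "") -> RMANOVAResult:
    """RM-ANOVA across timepoints + Dunnett comparisons vs the control timepoint.

    ``matrix`` is subjects x timepoints (percent values).  Subjects with any
    missing timepoint are dropped listwise and logged.  Contrast statistics
    use the within-subject error term,
    ``t_j = (mean_j - mean_control) / sqrt(2 * MS_error / n)`` with
    ``df = (n-1)(k-1)``; multiplicity-adjusted p-values come from the
    equicorrelated (rho = 1/2) multivariate-t distribution of the Dunnett
    procedure.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-D (subjects x timepoints)")
    complete = np.all(np.isfinite(X), axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.warning("rm_anova_dunnett: dropped %d subject(s) with gaps", n_dropped)
    X = X[complete]
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 complete subjects and >= 2 timepoints")
    if not (0 <= control_index < k):
        raise ValueError("control_index out of range")

    grand = X.mean()
    col_means = X.mean(axis=0)
    row_means = X.mean(axis=1)
    ss_time = n * np.sum((col_means - grand) ** 2)
    ss_subj = k * np.sum((row_means - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = ss_total - ss_time - ss_subj
    df_time = k - 1
    df_err = (n - 1) * (k - 1)
    ms_time = ss_time / df_time
    ms_err = max(ss_err / df_err, 0.0)
    if ms_err == 0.0:
        F = 0.0 if ms_time == 0.0 else np.inf
        p_f = 1.0 if ms_time == 0.0 else 0.0
    else:
        F = ms_time / ms_err
        p_f = float(sstats.f.sf(F, df_time, df_err))

    m = k - 1
    se = np.sqrt(2.0 * ms_err / n)
    timepoints: list[GroupStats] = []
    sems = X.std(axis=0, ddof=1) / np.sqrt(n)
    for j in range(k):
        if j == control_index:
            continue
        d = col_means[j] - col_means[control_index]
        if se == 0.0:
            t = 0.0 if d == 0.0 else np.sign(d) * np.inf
            p = 1.0 if d == 0.0 else 0.0
            degenerate = d != 0.0
        else:
            t = d / se
            p = float(np.clip(1.0 - _dunnett_prob(abs(t), m, df_err), 0.0, 1.0))
            degenerate = False
        timepoints.append(
            GroupStats(metric, n, float(col_means[j]), float(sems[j]),
                       "RM-ANOVA + Dunnett", float(t), float(p), df_err,
                       degenerate=degenerate)
        )
    return RMANOVAResult(float(F), df_time, df_err, p_f, float(ms_err), n,
                         control_index, timepoints, n_dropped)
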