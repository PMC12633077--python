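"""Between-group comparison of rhythm parameters and population-mean cosinor.

Two pooled single-cosinor fits (one per group) are compared parameter by
parameter — MESOR, amplitude, acrophase — with Wald-type F-ratios whose
degrees of freedom reflect the two populations and the total subject count:
the squared difference of estimates over the summed squared standard errors,
referred to F(1, n1 + n2 - 6), six being the coefficients consumed by the
two three-parameter fits.  Acrophase differences live on a circle, so the
numerator uses the signed circular difference, never the naive subtraction.

The population-mean cosinor averages the *linearized* coefficients
(M, beta, gamma) of several contributing fits and delinearizes the mean
vector, which is the only averaging that behaves correctly near the wrap:
averaging acrophase angles of 1 h and 23 h must give 0 h, not 12 h.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cosinor import CosinorFit, InvalidArgumentError, TestResult

__all__ = [
    "ComparisonTriple",
    "PopulationFit",
    "circular_diff_h",
    "compare_fits",
    "population_mean_cosinor",
    "timepoint_test",
    "bh_adjust",
]


@dataclass(frozen=True)
class ComparisonTriple:
    """The three parameter-wise tests comparing two groups' rhythms."""

    mesor_test: TestResult
    amplitude_test: TestResult
    acrophase_test: TestResult


@dataclass(frozen=True)
class PopulationFit:
    """Population-mean rhythm from k contributing cosinor fits.

    Means are taken over the linearized coefficients; amplitude and
    acrophase are delinearized from the mean (beta, gamma) vector.  Standard
    errors describe the between-fit scatter of the mean (empirical
    covariance / k, delta method) and are defined only for k >= 2.
    """

    k: int
    period_h: float
    mesor: float
    beta: float
    gamma: float
    amplitude: float
    acrophase_h: float
    mesor_se: float
    amplitude_se: float
    acrophase_se_h: float


def circular_diff_h(a1: float, a2: float, period_h: float) -> float:
    """Signed difference a1 - a2 on a circle of circumference ``period_h``,
    mapped into (-period/2, period/2]; the antipode maps to +period/2."""
    if not (np.isfinite(period_h) and period_h > 0):
        raise InvalidArgumentError(f"period_h must be finite and > 0, got {period_h}")
    d = float(np.mod(a1 - a2, period_h))
    if d > period_h / 2.0:
        d -= period_h
    return d


def _wald_f(diff: float, se1: float, se2: float, df2: int, kind: str) -> TestResult:
    var = se1**2 + se2**2
    if var == 0.0:
        if diff == 0.0:
            return TestResult(kind=kind, statistic=0.0, df1=1, df2=df2, p=1.0)
        return TestResult(
            kind=kind,
            statistic=float("inf"),
            df1=1,
            df2=df2,
            p=0.0,
            note="zero standard errors with nonzero difference",
        )
    f_stat = diff**2 / var
    p = float(stats.f.sf(f_stat, 1, df2))
    return TestResult(kind=kind, statistic=float(f_stat), df1=1, df2=df2, p=p)


def compare_fits(fit1: CosinorFit, fit2: CosinorFit) -> ComparisonTriple:
    """Compare MESOR, amplitude, and acrophase between two group fits.

    Both fits must share the period.  If either group's amplitude is
    numerically zero its acrophase is undefined and the acrophase test is
    returned as a flagged non-result (``defined=False``) instead of
    propagating NaN.
    """
    if fit1.period_h != fit2.period_h:
        raise InvalidArgumentError(
            f"period mismatch: {fit1.period_h} vs {fit2.period_h}"
        )
    df2 = fit1.n + fit2.n - 6
    mesor_t = _wald_f(fit1.mesor - fit2.mesor, fit1.mesor_se, fit2.mesor_se, df2, "mesor")
    if fit1.amplitude_defined and fit2.amplitude_defined:
        amp_t = _wald_f(
            fit1.amplitude - fit2.amplitude,
            fit1.amplitude_se,
            fit2.amplitude_se,
            df2,
            "amplitude",
        )
        d_acro = circular_diff_h(fit1.acrophase_h, fit2.acrophase_h, fit1.period_h)
        acro_t = _wald_f(d_acro, fit1.acrophase_se_h, fit2.acrophase_se_h, df2, "acrophase")
    else:
        amp_t = _wald_f(
            fit1.amplitude - fit2.amplitude,
            fit1.amplitude_se if fit1.amplitude_defined else 0.0,
            fit2.amplitude_se if fit2.amplitude_defined else 0.0,
            df2,
            "amplitude",
        ) if (fit1.amplitude_defined or fit2.amplitude_defined) else TestResult(
            kind="amplitude",
            statistic=float("nan"),
            df1=1,
            df2=df2,
            p=float("nan"),
            defined=False,
            note="amplitude numerically zero in both groups",
        )
        acro_t = TestResult(
            kind="acrophase",
            statistic=float("nan"),
            df1=1,
            df2=df2,
            p=float("nan"),
            defined=False,
            note="acrophase undefined (amplitude numerically zero)",
        )
    return ComparisonTriple(mesor_test=mesor_t, amplitude_test=amp_t, acrophase_test=acro_t)


def population_mean_cosinor(fits: Sequence[CosinorFit]) -> PopulationFit:
    """Average k cosinor fits into a population-mean rhythm.

    The mean is taken component-wise over each fit's (M, beta, gamma);
    amplitude and acrophase come from delinearizing the mean vector.
    Standard errors (k >= 2 only) use the empirical covariance of the
    contributing coefficient vectors divided by k, pushed through the delta
    method for the nonlinear parameters.
    """
    if len(fits) == 0:
        raise InvalidArgumentError("population_mean_cosinor requires at least one fit")
    periods = {f.period_h for f in fits}
    if len(periods) > 1:
        raise InvalidArgumentError(f"fits have mixed periods: {sorted(periods)}")
    period_h = fits[0].period_h
    k = len(fits)

    vecs = np.array([[f.mesor, f.beta, f.gamma] for f in fits])
    mesor, beta, gamma = (float(v) for v in vecs.mean(axis=0))
    amplitude = float(np.hypot(beta, gamma))
    phi = float(np.arctan2(-gamma, beta))
    acrophase_h = float(np.mod(-phi * period_h / (2.0 * np.pi), period_h))
    if acrophase_h >= period_h:  # mod can round up to the period
        acrophase_h = 0.0

    if k >= 2 and amplitude > 0:
        cov = np.cov(vecs, rowvar=False) / k  # covariance of the mean
        mesor_se = float(np.sqrt(cov[0, 0]))
        cov_bg = cov[1:, 1:]
        g_amp = np.array([beta, gamma]) / amplitude
        amplitude_se = float(np.sqrt(g_amp @ cov_bg @ g_amp))
        g_phi = np.array([gamma, -beta]) / amplitude**2
        acrophase_se_h = float(np.sqrt(g_phi @ cov_bg @ g_phi)) * period_h / (2.0 * np.pi)
    elif k >= 2:
        cov = np.cov(vecs, rowvar=False) / k
        mesor_se = float(np.sqrt(cov[0, 0]))
        amplitude_se = float("nan")
        acrophase_se_h = float("nan")
    else:
        mesor_se = amplitude_se = acrophase_se_h = float("nan")

    return PopulationFit(
        k=k,
        period_h=period_h,
        mesor=mesor,
        beta=beta,
        gamma=gamma,
        amplitude=amplitude,
        acrophase_h=acrophase_h,
        mesor_se=mesor_se,
        amplitude_se=amplitude_se,
        acrophase_se_h=acrophase_se_h,
    )


def timepoint_test(
    values1: Sequence[float], values2: Sequence[float], pooled: bool = True
) -> TestResult:
    """Two-sample Student's t-test between groups at one timepoint.

    Pooled-variance by default (``pooled=False`` gives Welch).  Degenerate
    zero-variance inputs are handled explicitly: identical constant groups
    give p = 1; constant groups with different means give p = 0 flagged
    ``degenerate``.
    """
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    if v1.size < 2 or v2.size < 2:
        raise InvalidArgumentError("each group needs at least 2 values")
    df = v1.size + v2.size - 2
    pooled_ss = float(np.sum((v1 - v1.mean()) ** 2) + np.sum((v2 - v2.mean()) ** 2))
    if pooled_ss == 0.0:
        if v1.mean() == v2.mean():
            return TestResult(kind="timepoint_t", statistic=0.0, df1=1, df2=df, p=1.0)
        return TestResult(
            kind="timepoint_t",
            statistic=float("inf"),
            df1=1,
            df2=df,
            p=0.0,
            note="degenerate: zero pooled variance, nonzero difference",
        )
    res = stats.ttest_ind(v1, v2, equal_var=pooled)
    return TestResult(
        kind="timepoint_t",
        statistic=float(res.statistic),
        df1=1,
        df2=float(res.df),
        p=float(res.pvalue),
    )


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment.

    Returns the adjusted p-values in the original order:
    sort ascending, q(i) = min_{j>=i} p(j)*m/j, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InvalidArgumentError("p-values must all lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q
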