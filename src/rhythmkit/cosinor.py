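"""Single-cosinor model fitting and zero-amplitude rhythm detection.

The single-cosinor model describes a circadian (or other periodic) signal as

    Y(t) = M + A * cos(2*pi*t/tau + phi) + e,   e ~ N(0, sigma^2)

where ``M`` is the MESOR (midline estimating statistic of rhythm, the
rhythm-adjusted mean), ``A >= 0`` the amplitude (half the peak-to-trough
extent), ``phi`` the acrophase angle in radians, and ``tau`` the period in
hours.  Substituting beta = A*cos(phi), gamma = -A*sin(phi) linearizes the
model into an ordinary least-squares regression of the measurements on the
regressors (1, cos(2*pi*t/tau), sin(2*pi*t/tau)); the rhythm parameters are
recovered from (beta, gamma) afterwards.  Acrophase is reported as peak clock
time in hours on [0, tau), the convention used when tabulating rhythms
against zeitgeber time, with the radian angle retained internally.

The period is fixed (default 24 h), never estimated: with a cross-sectional
design of a few timepoints per cycle there is no information to estimate it,
and the downstream group comparisons require a common period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DEFAULT_PERIOD_H",
    "AMPLITUDE_TOL_REL",
    "InvalidArgumentError",
    "DesignError",
    "InsufficientDataError",
    "TimeSample",
    "CosinorFit",
    "TestResult",
    "linearize_time",
    "fit_single_cosinor",
    "zero_amplitude_test",
    "predict",
]

#: Fixed analysis period in hours.
DEFAULT_PERIOD_H: float = 24.0

#: Relative threshold below which a fitted amplitude is treated as zero and
#: the acrophase as undefined: A < AMPLITUDE_TOL_REL * max(1, |M|).
AMPLITUDE_TOL_REL: float = 1e-10


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class DesignError(InvalidArgumentError):
    """The sampling design cannot identify the cosinor coefficients
    (fewer than 3 distinct timepoints modulo the period)."""


class InsufficientDataError(InvalidArgumentError):
    """Too few observations to fit the three-coefficient model."""


@dataclass(frozen=True)
class TimeSample:
    """One cross-sectional measurement: a subject sampled once at a
    clock time, yielding a single value for one feature."""

    subject_id: str
    group: str
    time_h: float
    value: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.time_h) and math.isfinite(self.value)):
            raise InvalidArgumentError(
                f"non-finite sample ({self.subject_id}): "
                f"time_h={self.time_h}, value={self.value}"
            )


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    ``kind`` labels the test family (``zero_amplitude``, ``mesor``,
    ``amplitude``, ``acrophase``, ``timepoint_t``, ``permanova``).
    ``defined`` is False for flagged non-results (e.g. an acrophase
    comparison when one group has no detectable rhythm); such results carry
    NaN statistics and are never silently propagated into arithmetic.
    ``note`` records degeneracies (perfect fit, zero pooled variance).
    """

    kind: str
    statistic: float
    df1: float
    df2: float
    p: float
    defined: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if self.defined and not (0.0 <= self.p <= 1.0):
            raise InvalidArgumentError(f"p-value {self.p} outside [0, 1]")


@dataclass(frozen=True)
class CosinorFit:
    """A fitted single-cosinor model for one (group, feature) stratum.

    ``beta`` and ``gamma`` are the linearized cosine/sine coefficients;
    ``cov3`` is the 3x3 OLS covariance of (M, beta, gamma), from which the
    amplitude and acrophase standard errors are obtained by the delta
    method.  When the fitted amplitude is numerically zero the acrophase is
    meaningless: ``amplitude_defined`` is False and the acrophase fields are
    NaN.
    """

    period_h: float
    n: int
    mesor: float
    mesor_se: float
    amplitude: float
    amplitude_se: float
    acrophase_h: float
    acrophase_se_h: float
    beta: float
    gamma: float
    phi: float
    cov3: np.ndarray = field(repr=False)
    sigma2: float
    rss: float
    mss: float
    r2: float
    amplitude_defined: bool = True


def linearize_time(
    time_h: float | np.ndarray, period_h: float
) -> tuple[np.ndarray, np.ndarray]:
    """Map clock time onto the unit-circle regressors of the linearized
    cosinor model: ``x = cos(2*pi*t/tau)``, ``z = sin(2*pi*t/tau)``.

    Parameters
    ----------
    time_h : scalar or array of clock times in hours.
    period_h : the rhythm period tau, hours, > 0.

    Returns
    -------
    (x, z) : the cosine and sine regressor values, each in [-1, 1].
    """
    time_h = np.asarray(time_h, dtype=float)
    if not (np.isfinite(period_h) and period_h > 0):
        raise InvalidArgumentError(f"period_h must be finite and > 0, got {period_h}")
    if not np.all(np.isfinite(time_h)):
        raise InvalidArgumentError("time_h contains non-finite values")
    omega_t = 2.0 * np.pi * time_h / period_h
    return np.cos(omega_t), np.sin(omega_t)


def _coerce_samples(
    samples: Sequence[TimeSample] | tuple[np.ndarray, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Accept either a sequence of TimeSample or an (times, values) pair."""
    if isinstance(samples, tuple) and len(samples) == 2:
        t = np.asarray(samples[0], dtype=float)
        y = np.asarray(samples[1], dtype=float)
    else:
        t = np.array([s.time_h for s in samples], dtype=float)
        y = np.array([s.value for s in samples], dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise InvalidArgumentError("times and values must be 1-D and equal length")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise InvalidArgumentError("non-finite time or value in input")
    return t, y


def _n_distinct_timepoints(time_h: np.ndarray, period_h: float) -> int:
    # distinct modulo the period, with a tolerance robust to float time labels
    folded = np.sort(np.mod(time_h, period_h))
    tol = 1e-9 * period_h
    if folded.size == 0:
        return 0
    distinct = 1 + int(np.count_nonzero(np.diff(folded) > tol))
    # the fold point: first and last may coincide across the wrap
    if distinct > 1 and (folded[-1] - folded[0]) > period_h - tol:
        distinct -= 1
    return distinct


def fit_single_cosinor(
    samples: Sequence[TimeSample] | tuple[np.ndarray, np.ndarray],
    period_h: float = DEFAULT_PERIOD_H,
) -> CosinorFit:
    """Fit the single-cosinor model by ordinary least squares.

    Parameters
    ----------
    samples : sequence of :class:`TimeSample`, or an ``(times, values)``
        pair of 1-D arrays (hours, measurement units).
    period_h : fixed period tau in hours (default 24).

    Returns
    -------
    :class:`CosinorFit` with rhythm parameters, delta-method standard
    errors, and fit diagnostics.

    Raises
    ------
    InsufficientDataError
        if fewer than 4 observations are supplied.
    DesignError
        if fewer than 3 distinct timepoints (mod period) are present, in
        which case the design matrix is rank-deficient and the coefficients
        are not identifiable.
    """
    t, y = _coerce_samples(samples)
    n = t.size
    if n < 4:
        raise InsufficientDataError(f"need at least 4 observations, got {n}")
    if _n_distinct_timepoints(t, period_h) < 3:
        raise DesignError(
            "design is rank-deficient: need >= 3 distinct timepoints "
            f"modulo the period ({period_h} h)"
        )

    x, z = linearize_time(t, period_h)
    X = np.column_stack([np.ones(n), x, z])
    if np.linalg.matrix_rank(X) < 3:
        raise DesignError("design matrix is rank-deficient")

    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    mesor, beta, gamma = (float(c) for c in coef)

    fitted = X @ coef
    resid = y - fitted
    rss = float(resid @ resid)
    ybar = float(np.mean(y))
    mss = float(np.sum((fitted - ybar) ** 2))
    tss = mss + rss
    r2 = mss / tss if tss > 0 else 0.0
    r2 = min(max(r2, 0.0), 1.0)

    dof = n - 3
    sigma2 = rss / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    cov3 = sigma2 * xtx_inv
    mesor_se = float(np.sqrt(cov3[0, 0]))

    amplitude = float(np.hypot(beta, gamma))
    phi = float(np.arctan2(-gamma, beta))  # in (-pi, pi]
    defined = amplitude >= AMPLITUDE_TOL_REL * max(1.0, abs(mesor))

    if defined:
        acrophase_h = float(np.mod(-phi * period_h / (2.0 * np.pi), period_h))
        if acrophase_h >= period_h:  # mod can round up to the period
            acrophase_h = 0.0
        # delta method on (beta, gamma):
        #   A = sqrt(b^2 + g^2)      -> grad (b/A, g/A)
        #   phi = atan2(-g, b)       -> grad (g/A^2, -b/A^2)
        cov_bg = cov3[1:, 1:]
        g_amp = np.array([beta, gamma]) / amplitude
        amplitude_se = float(np.sqrt(g_amp @ cov_bg @ g_amp))
        g_phi = np.array([gamma, -beta]) / amplitude**2
        phi_se = float(np.sqrt(g_phi @ cov_bg @ g_phi))
        acrophase_se_h = phi_se * period_h / (2.0 * np.pi)
    else:
        acrophase_h = float("nan")
        amplitude_se = float("nan")
        acrophase_se_h = float("nan")

    return CosinorFit(
        period_h=float(period_h),
        n=n,
        mesor=mesor,
        mesor_se=mesor_se,
        amplitude=amplitude,
        amplitude_se=amplitude_se,
        acrophase_h=acrophase_h,
        acrophase_se_h=acrophase_se_h,
        beta=beta,
        gamma=gamma,
        phi=phi,
        cov3=cov3,
        sigma2=sigma2,
        rss=rss,
        mss=mss,
        r2=r2,
        amplitude_defined=defined,
    )


def zero_amplitude_test(fit: CosinorFit) -> TestResult:
    """F-test of the null hypothesis that the amplitude is zero.

    Tests the joint contribution of the cosine and sine regressors beyond
    the intercept: ``F = (MSS/2) / (RSS/(n-3))`` referred to F(2, n-3).
    A perfect fit (RSS numerically zero with nonzero model sum of squares)
    returns p = 0 with an infinite statistic rather than dividing by zero.
    """
    if fit.n < 4:
        raise InsufficientDataError("zero-amplitude test needs n >= 4")
    dof = fit.n - 3
    tss = fit.mss + fit.rss
    # flat data: total variation at machine zero relative to the data scale
    if tss <= 1e-20 * fit.n * max(1.0, fit.mesor**2):
        return TestResult(
            kind="zero_amplitude", statistic=0.0, df1=2, df2=dof, p=1.0
        )
    # RSS at machine zero relative to the data scale means a perfect fit
    if fit.rss <= 1e-20 * tss or fit.rss == 0.0:
        return TestResult(
            kind="zero_amplitude",
            statistic=float("inf"),
            df1=2,
            df2=dof,
            p=0.0,
            note="perfect fit (rss = 0)",
        )
    f_stat = (fit.mss / 2.0) / (fit.rss / dof)
    p = float(stats.f.sf(f_stat, 2, dof))
    return TestResult(kind="zero_amplitude", statistic=float(f_stat), df1=2, df2=dof, p=p)


def predict(fit: CosinorFit, time_h: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the fitted rhythm ``M + A*cos(2*pi*t/tau + phi)`` at clock
    time(s) ``time_h``.  The maximum M + A is attained at the acrophase."""
    time_h = np.asarray(time_h, dtype=float)
    if not np.all(np.isfinite(time_h)):
        raise InvalidArgumentError("time_h contains non-finite values")
    out = fit.mesor + fit.amplitude * np.cos(
        2.0 * np.pi * time_h / fit.period_h + fit.phi
    )
    return float(out) if out.ndim == 0 else out
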