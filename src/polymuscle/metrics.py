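"""Error metrics, Chebyshev outlier screening, complexity regressions.

Fit quality is reported as a normalized RMS percentage (residual RMS over a
reference scale: the length range of motion or the maximum moment-arm
magnitude).  Outliers among absolute errors are screened with a maximum
expected error (MEE) threshold derived from Chebyshev's inequality, which
holds for arbitrarily-shaped (non-normal) error distributions:

    MEE = mean(|e|) + (1/alpha) * sd(|e|)

With ``alpha = 0.1`` the threshold sits 10 standard deviations out, outside
99% of any distribution (1 - 1/k^2 = 0.99 at k = 10).

The complexity analysis relates the number of selected polynomial terms to
the number of DOFs a muscle spans, with linear and free two-parameter
exponential fits, screening outlying muscles by Tukey's rule on the
residuals of both preliminary fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .terms import full_size

logger = logging.getLogger(__name__)


def normalized_rms(predicted, observed, normalizer: float) -> float:
    """Normalized RMS error in percent: ``100 * RMS(residual) / normalizer``."""
    if normalizer <= 0:
        raise ValueError("normalizer must be positive")
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    return float(100.0 * np.sqrt(np.mean((predicted - observed) ** 2)) / normalizer)


def mee_outliers(
    abs_errors, alpha: float = 0.1
) -> Tuple[float, np.ndarray]:
    """Maximum-expected-error threshold and outlier mask.

    ``MEE = mean + (1/alpha) * sd`` of the absolute errors; samples above
    the threshold are flagged.  By Chebyshev's inequality at most
    ``alpha**2`` of any population exceeds the threshold, whatever its
    distribution.  A single sample has no spread estimate and flags nothing.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    e = np.abs(np.asarray(abs_errors, dtype=float))
    if e.size == 0:
        raise ValueError("empty error vector")
    if e.size == 1:
        return float(e[0]), np.zeros(1, dtype=bool)
    mee = float(np.mean(e) + (1.0 / alpha) * np.std(e, ddof=1))
    return mee, e > mee


@dataclass(frozen=True)
class ComplexityRegression:
    """Linear and exponential fits of term count vs DOF count.

    ``linear = (slope, intercept)`` for ``y = b*x + c``;
    ``exponential = (b, c)`` for ``y = b * exp(c*x)``.  ``r``/``p`` are the
    Pearson correlation between fit and data and its t-distribution
    p-value.  ``outliers`` are indices removed by Tukey's rule (residual
    above median + 1.5 IQR in both preliminary fits) before the final fits.
    """

    linear: Tuple[float, float]
    linear_r: float
    linear_p: float
    exponential: Tuple[float, float]
    exponential_r: float
    exponential_p: float
    outliers: Tuple[int, ...]


def _corr_pvalue(pred: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    if np.std(pred) == 0 or np.std(y) == 0:
        return 0.0, 1.0
    r, p = stats.pearsonr(pred, y)
    return float(r), float(p)


def _exp_fit(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    # log-linear start, then free 2-parameter refinement
    pos = y > 0
    if pos.sum() >= 2 and np.std(x[pos]) > 0:
        c0, logb0 = np.polyfit(x[pos], np.log(y[pos]), 1)
    else:
        c0, logb0 = 0.1, np.log(max(np.mean(y), 1e-6))
    try:
        popt, _ = optimize.curve_fit(
            lambda t, b, c: b * np.exp(c * t), x, y,
            p0=[np.exp(logb0), c0], maxfev=10000,
        )
        return float(popt[0]), float(popt[1])
    except RuntimeError:
        return float(np.exp(logb0)), float(c0)


def _tukey_high(residuals: np.ndarray) -> np.ndarray:
    med = np.median(residuals)
    iqr = np.subtract(*np.percentile(residuals, [75, 25]))
    return residuals > med + 1.5 * iqr


def complexity_regression(
    term_counts: Sequence[float], dof_counts: Sequence[float]
) -> ComplexityRegression:
    """Fit term count as linear and exponential functions of DOF count.

    Muscles whose absolute residuals exceed median + 1.5 IQR under *both*
    preliminary fits are removed before the final fits (Tukey's rule).
    """
    y = np.asarray(term_counts, dtype=float)
    x = np.asarray(dof_counts, dtype=float)
    if y.size < 3 or y.size != x.size:
        raise ValueError("need at least 3 paired (term, DOF) counts")
    if np.ptp(x) == 0:
        raise ValueError("degenerate DOF counts (all equal)")

    slope0, icpt0 = np.polyfit(x, y, 1)
    res_lin = np.abs(y - (slope0 * x + icpt0))
    b0, c0 = _exp_fit(x, y)
    res_exp = np.abs(y - b0 * np.exp(c0 * x))
    out_mask = _tukey_high(res_lin) & _tukey_high(res_exp)
    keep = ~out_mask
    if keep.sum() < 3:
        keep = np.ones_like(out_mask)
        out_mask = ~keep
        logger.warning("Tukey screening would leave <3 muscles; kept all")

    xk, yk = x[keep], y[keep]
    slope, icpt = np.polyfit(xk, yk, 1)
    lin_r, lin_p = _corr_pvalue(slope * xk + icpt, yk)
    b, c = _exp_fit(xk, yk)
    exp_r, exp_p = _corr_pvalue(b * np.exp(c * xk), yk)
    return ComplexityRegression(
        linear=(float(slope), float(icpt)),
        linear_r=lin_r, linear_p=lin_p,
        exponential=(b, c),
        exponential_r=exp_r, exponential_p=exp_p,
        outliers=tuple(int(i) for i in np.flatnonzero(out_mask)),
    )


def relative_complexity(term_count: int, d: int, rho: int) -> float:
    """Share of the full parameter space a structure occupies, in percent:
    ``100 * term_count / C(d + rho, rho)`` (intercept included in the full
    count: a full 2-variable power-2 polynomial has 6 terms, so a 3-term
    structure has relative complexity 50%)."""
    size = full_size(d, rho)
    if term_count > size:
        raise ValueError(f"term count {term_count} exceeds full size {size}")
    return 100.0 * term_count / size


@dataclass(frozen=True)
class ErrorSummary:
    """Normalized RMS summary for one quantity across muscles."""

    quantity: str
    rms_mean: float
    rms_sd: float
    outlier_fraction: float
    per_muscle: Tuple[Tuple[str, float], ...]


def summarize_errors(
    per_muscle_rms: Sequence[Tuple[str, float]],
    pooled_abs_errors: np.ndarray,
    quantity: str,
    alpha: float = 0.1,
) -> ErrorSummary:
    """Mean ± sd of per-muscle normalized RMS plus the pooled MEE outlier
    fraction for one quantity (lengths or moment arms)."""
    rms = np.array([v for _n, v in per_muscle_rms], dtype=float)
    _mee, mask = mee_outliers(pooled_abs_errors, alpha=alpha)
    return ErrorSummary(
        quantity=quantity,
        rms_mean=float(np.mean(rms)),
        rms_sd=float(np.std(rms, ddof=1)) if rms.size > 1 else 0.0,
        outlier_fraction=float(np.mean(mask)),
        per_muscle=tuple((n, float(v)) for n, v in per_muscle_rms),
    )
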