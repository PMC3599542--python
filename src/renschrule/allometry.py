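"""Model I (OLS) and Model II (reduced major axis) log-log allometry.

The allometric question is whether male size scales hyperallometrically
(slope > 1 on log-log axes) with female size — Rensch's rule — or
isometrically (slope = 1).  Both sexes' means carry comparable error, so
the reduced major axis (RMA) estimator, whose slope magnitude is
sd(y)/sd(x), is the appropriate Model II fit; OLS is provided for
comparison.  Through-origin variants serve phylogenetically independent
contrasts, whose signs are arbitrary and whose regressions must not be
mean-centred.

Confidence intervals are slope ± t_crit(df) · SE at the 95% level; the
RMA slope SE equals the OLS slope SE (the classical large-sample result),
with df = n - 2 (n - 1 through the origin).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._errors import DegenerateInputError, InsufficientDataError

HYPER = "hyperallometric"
HYPO = "hypoallometric"

CONFIDENCE_LEVEL = 0.95


@dataclass(frozen=True)
class RegressionFit:
    """A fitted bivariate line with inference on the slope.

    ``ci95`` is slope ± t_crit(df[1]) · slope_se.  ``intercept`` is None
    for through-origin fits.  ``df`` is (numerator, denominator) of the
    overall F test.
    """

    model: str  # "OLS" | "RMA"
    through_origin: bool
    slope: float
    slope_se: float
    ci95: tuple[float, float]
    intercept: float | None
    r2: float
    f_stat: float
    p_value: float
    df: tuple[int, int]
    n: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        intercept = 0.0 if self.intercept is None else self.intercept
        return self.slope * np.asarray(x, dtype=float) + intercept


@dataclass(frozen=True)
class IsometryVerdict:
    """Does the 95% CI of the slope include 1 (isometry)?"""

    slope_fit: RegressionFit
    isometric: bool
    direction_if_rejected: str  # hyperallometric | hypoallometric | none


def _prepare(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray, int]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < min_n:
        raise InsufficientDataError(f"need at least {min_n} points, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    return x, y, n


def _ci(slope: float, se: float, df_den: int) -> tuple[float, float]:
    half = stats.t.ppf(0.5 + CONFIDENCE_LEVEL / 2.0, df_den) * se
    return (slope - half, slope + half)


def fit_ols(x, y, through_origin: bool = False) -> RegressionFit:
    """Ordinary least squares of y on x (Model I).

    ``through_origin=True`` uses the no-intercept estimator Σxy/Σx² with
    n-1 denominator degrees of freedom and an uncentred R².
    """
    x, y, n = _prepare(x, y, min_n=3)
    if through_origin:
        sxx = float(np.dot(x, x))
        if sxx == 0.0:
            raise DegenerateInputError("x is identically zero")
        slope = float(np.dot(x, y)) / sxx
        resid = y - slope * x
        df_den = n - 1
        sse = float(np.dot(resid, resid))
        syy = float(np.dot(y, y))
        s2 = sse / df_den
        se = float(np.sqrt(s2 / sxx)) if s2 > 0 else 0.0
        r2 = 1.0 - sse / syy if syy > 0 else 1.0
        f_stat = (syy - sse) / s2 if s2 > 0 else np.inf
        intercept = None
    else:
        if np.ptp(x) == 0.0:
            raise DegenerateInputError("x is constant; OLS slope undefined")
        xc = x - x.mean()
        yc = y - y.mean()
        sxx = float(np.dot(xc, xc))
        sxy = float(np.dot(xc, yc))
        syy = float(np.dot(yc, yc))
        slope = sxy / sxx
        intercept = float(y.mean() - slope * x.mean())
        resid = yc - slope * xc
        df_den = n - 2
        sse = float(np.dot(resid, resid))
        s2 = sse / df_den
        se = float(np.sqrt(s2 / sxx)) if s2 > 0 else 0.0
        r2 = 1.0 - sse / syy if syy > 0 else 1.0
        f_stat = (syy - sse) / s2 if s2 > 0 else np.inf
    p = float(stats.f.sf(f_stat, 1, df_den)) if np.isfinite(f_stat) else 0.0
    return RegressionFit(
        model="OLS",
        through_origin=through_origin,
        slope=float(slope),
        slope_se=se,
        ci95=_ci(float(slope), se, df_den),
        intercept=intercept,
        r2=float(r2),
        f_stat=float(f_stat),
        p_value=p,
        df=(1, df_den),
        n=n,
    )


def fit_rma(x, y, through_origin: bool = False) -> RegressionFit:
    """Reduced major axis fit (Model II): |slope| = sd(y)/sd(x).

    The slope sign follows the sign of the correlation (of Σxy through
    the origin).  The slope SE equals the OLS slope SE and the CI uses
    Student's t with n-2 df (n-1 through the origin).
    """
    x, y, n = _prepare(x, y, min_n=3)
    if through_origin:
        sxx = float(np.dot(x, x))
        syy = float(np.dot(y, y))
        sxy = float(np.dot(x, y))
        if sxx == 0.0 or syy == 0.0:
            raise DegenerateInputError("zero sum of squares in x or y")
        if sxy == 0.0:
            raise DegenerateInputError(
                "Σxy is exactly zero; RMA slope sign is ambiguous"
            )
        r = sxy / np.sqrt(sxx * syy)
        slope = float(np.sign(sxy) * np.sqrt(syy / sxx))
        intercept = None
        df_den = n - 1
    else:
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            raise DegenerateInputError("constant x or y; RMA slope undefined")
        xc = x - x.mean()
        yc = y - y.mean()
        sxx = float(np.dot(xc, xc))
        syy = float(np.dot(yc, yc))
        sxy = float(np.dot(xc, yc))
        if sxy == 0.0:
            raise DegenerateInputError(
                "correlation is exactly zero; RMA slope sign is ambiguous"
            )
        r = sxy / np.sqrt(sxx * syy)
        slope = float(np.sign(r) * np.sqrt(syy / sxx))
        intercept = float(y.mean() - slope * x.mean())
        df_den = n - 2
    r2 = float(r * r)
    se = float(abs(slope) * np.sqrt((1.0 - r2) / df_den)) if r2 < 1.0 else 0.0
    f_stat = r2 * df_den / (1.0 - r2) if r2 < 1.0 else np.inf
    p = float(stats.f.sf(f_stat, 1, df_den)) if np.isfinite(f_stat) else 0.0
    return RegressionFit(
        model="RMA",
        through_origin=through_origin,
        slope=slope,
        slope_se=se,
        ci95=_ci(slope, se, df_den),
        intercept=intercept,
        r2=r2,
        f_stat=float(f_stat),
        p_value=p,
        df=(1, df_den),
        n=n,
    )


def test_isometry(fit: RegressionFit) -> IsometryVerdict:
    """Check whether a slope of unity lies inside the fit's 95% CI.

    With y = log10(male size) and x = log10(female size), rejection with
    slope > 1 (hyperallometry) is the signature of Rensch's rule in
    female-biased taxa; slope < 1 is its inverse.
    """
    low, high = fit.ci95
    if not (np.isfinite(fit.slope_se) and np.isfinite(low) and np.isfinite(high)):
        raise ValueError("fit must have finite slope SE and CI")
    isometric = bool(low <= 1.0 <= high)
    if isometric:
        direction = "none"
    else:
        direction = HYPER if low > 1.0 else HYPO
    return IsometryVerdict(
        slope_fit=fit, isometric=isometric, direction_if_rejected=direction
    )
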