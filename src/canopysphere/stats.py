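"""Comparison and error-analysis statistics.

Covers the method-comparison toolkit: ordinary least squares with R²,
regression standard error SE = sqrt(SSR/(N-2)) and relative standard error
RSE = SE/ȳ·100; Welch's unequal-variance t-test computed from group
summaries (mean, variance, n); and the blue-band exposure metric (mean raw
blue intensity over the image disc), used to attribute residual variance
between two cameras to exposure differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "WelchResult",
    "linear_fit",
    "welch_from_summary",
    "exposure_metric",
]


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    se: float           # units of y
    rse_pct: float      # SE / mean(y) * 100
    n: int


@dataclass
class WelchResult:
    t: float
    df: float           # Welch-Satterthwaite degrees of freedom
    p_two_tailed: float


def linear_fit(x, y) -> RegressionResult:
    """OLS y ~ x with R², SE and relative SE.

    SE = sqrt(SSR/(N-2)); RSE = SE/ȳ·100, expressing the regression
    scatter as a percentage of the mean response.  Requires N >= 3 (SE is
    undefined otherwise) and non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant x: slope undefined")
    res = sps.linregress(x, y)
    yhat = res.intercept + res.slope * x
    ssr = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else 0.0
    se = np.sqrt(ssr / (n - 2))
    ybar = float(y.mean())
    if ybar == 0:
        raise ValueError("mean of y is zero: relative SE undefined")
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(r2),
        se=float(se),
        rse_pct=float(se / ybar * 100.0),
        n=int(n),
    )


def welch_from_summary(
    mean1: float, var1: float, n1: int, mean2: float, var2: float, n2: int
) -> WelchResult:
    """Welch's two-sample t-test from group summary statistics.

    t = (m1 - m2)/sqrt(v1/n1 + v2/n2); degrees of freedom by
    Welch-Satterthwaite; two-tailed p from the exact t distribution.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if var1 <= 0 or var2 <= 0:
        raise ValueError("group variances must be positive")
    se1 = var1 / n1
    se2 = var2 / n2
    t = (mean1 - mean2) / np.sqrt(se1 + se2)
    df = (se1 + se2) ** 2 / (se1**2 / (n1 - 1) + se2**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p_two_tailed=float(p))


def exposure_metric(image: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Mean blue-channel intensity over inside pixels, on the raw 0-255 scale.

    No gamma linearization: the metric summarizes the stored histogram as
    the camera exposed it.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected a 3-channel RGB raster")
    blue = img[..., 2]
    if mask is None:
        return float(blue.mean())
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return float(blue[mask].mean())
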