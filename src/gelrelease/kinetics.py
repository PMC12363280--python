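"""Korsmeyer-Peppas analysis of the early release window.

The empirical power law ``M_t / M_inf = a t^n`` is fitted to the first
hours of a cumulative release curve by ordinary least squares on the
log-log linearization ``ln(M_t/M_inf) = ln a + n ln t``.  For a
cylindrical device the exponent separates the transport regimes:
``n <= 0.45`` Fickian diffusion, ``0.45 < n < 0.89`` anomalous
(diffusion + erosion), ``n >= 0.89`` erosion-controlled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .curves import ReleaseCurve, r_squared
from .exceptions import InsufficientDataError, InvalidParameterError

__all__ = ["KPFit", "fit_korsmeyer_peppas", "classify_mechanism", "MECHANISM_THRESHOLDS"]

#: cylindrical-geometry exponent thresholds (fickian upper bound, erosion lower bound)
MECHANISM_THRESHOLDS = (0.45, 0.89)

#: default fitting window upper bound, hours
DEFAULT_WINDOW_H = 6.0


@dataclass(frozen=True)
class KPFit:
    """Result of a Korsmeyer-Peppas log-log regression.

    a : prefactor in fraction * h^-n (released *fraction*, not percent)
    n : release exponent (dimensionless)
    r_squared : coefficient of determination of the linearized fit
    window_h : upper bound of the fitting window (h)
    mechanism : 'fickian' | 'anomalous' | 'erosion'
    n_points : number of observations used
    """

    a: float
    n: float
    r_squared: float
    window_h: float
    mechanism: str
    n_points: int


def classify_mechanism(n: float) -> str:
    """Classify the release mechanism from the exponent of a cylindrical device.

    ``n <= 0.45`` -> ``'fickian'`` (values below 0.45 still indicate
    diffusion, with solute/matrix interactions); ``0.45 < n < 0.89`` ->
    ``'anomalous'``; ``n >= 0.89`` -> ``'erosion'``.  Total over finite n.
    """
    if not math.isfinite(n):
        raise InvalidParameterError(f"exponent must be finite, got {n}")
    lo, hi = MECHANISM_THRESHOLDS
    if n <= lo:
        return "fickian"
    if n < hi:
        return "anomalous"
    return "erosion"


def fit_korsmeyer_peppas(curve: ReleaseCurve, window_h: float = DEFAULT_WINDOW_H) -> KPFit:
    """Fit ``M_t/M_inf = a t^n`` over ``(0, window_h]`` by log-log OLS.

    Points with ``t = 0`` or zero cumulative release are excluded (their
    logarithm is undefined); at least 3 usable points are required.
    Natural logarithms are used; the intercept is back-transformed so
    ``a`` is a fraction per h^n.
    """
    if not window_h > 0:
        raise InvalidParameterError(f"window_h must be > 0, got {window_h}")
    t = curve.times
    frac = curve.cumulative_fraction
    use = (t > 0) & (t <= window_h) & (frac > 0)
    if use.sum() < 3:
        raise InsufficientDataError(
            f"Korsmeyer-Peppas fit needs >= 3 points with t > 0 and release > 0 "
            f"inside the {window_h} h window; got {int(use.sum())}"
        )
    x = np.log(t[use])
    y = np.log(frac[use])
    slope, intercept = np.polyfit(x, y, 1)
    r2 = r_squared(y, slope * x + intercept)
    n = float(slope)
    return KPFit(
        a=float(np.exp(intercept)),
        n=n,
        r_squared=float(r2),
        window_h=float(window_h),
        mechanism=classify_mechanism(n),
        n_points=int(use.sum()),
    )
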