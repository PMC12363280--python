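"""Release-curve containers and basic release statistics.

The central exchange object of every stage is :class:`ReleaseCurve`: a
time series of cumulative released mass, expressed both in absolute
units (µg) and as a percentage of the initial loading ``M_inf``.  Under
the sampling protocol emulated here the complete supernatant is
collected (and replaced) at each observation time, so the measured
quantity is the per-interval released mass; :func:`cumulative_from_supernatants`
assembles the cumulative curve from those interval masses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    DataQualityWarning,
    InvalidParameterError,
    UndefinedStatisticError,
)

__all__ = [
    "ReleaseCurve",
    "SupernatantSeries",
    "cumulative_from_supernatants",
    "r_squared",
]


@dataclass(frozen=True)
class ReleaseCurve:
    """Cumulative release of a solute over time.

    Parameters
    ----------
    times : array of float
        Observation times in hours, non-decreasing.
    cumulative_mass : array of float
        Cumulative released mass at each time, in µg.
    m_infinity : float
        Initial loaded mass ``M_inf`` in µg (100% reference).
    """

    times: np.ndarray
    cumulative_mass: np.ndarray
    m_infinity: float
    #: optional solver diagnostics attached by ``solve_release(track_flux=True)``:
    #: (step times s, profile-integral released mass, flux-integral released mass)
    diagnostics: dict | None = field(default=None, compare=False, repr=False)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        m = np.asarray(self.cumulative_mass, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "cumulative_mass", m)
        if t.ndim != 1 or m.shape != t.shape:
            raise InvalidParameterError("times and cumulative_mass must be 1-D and equal length")
        if t.size and np.any(np.diff(t) < 0):
            raise InvalidParameterError("times must be non-decreasing")
        if not self.m_infinity > 0:
            raise InvalidParameterError(f"m_infinity must be > 0, got {self.m_infinity}")

    @property
    def cumulative_percent(self) -> np.ndarray:
        """``100 * M_t / M_inf`` at each observation time."""
        return 100.0 * self.cumulative_mass / self.m_infinity

    @property
    def cumulative_fraction(self) -> np.ndarray:
        return self.cumulative_mass / self.m_infinity

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class SupernatantSeries:
    """Per-interval released masses from complete supernatant collection.

    ``masses[i]`` is the mass (µg) recovered in the supernatant collected
    at ``times[i]``; ``m_initial`` is the loaded mass (µg).
    """

    times: np.ndarray
    masses: np.ndarray
    m_initial: float

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        m = np.asarray(self.masses, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "masses", m)
        if t.ndim != 1 or m.shape != t.shape:
            raise InvalidParameterError("times and masses must be 1-D and equal length")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if np.any(m < 0):
            raise InvalidParameterError("interval masses must be >= 0")
        if not self.m_initial > 0:
            raise InvalidParameterError("m_initial must be > 0")


def cumulative_from_supernatants(
    series: SupernatantSeries, *, over_100_tolerance_pct: float = 5.0
) -> ReleaseCurve:
    """Assemble a cumulative release curve from supernatant interval masses.

    The cumulative percent at observation ``t`` is
    ``100 * sum_{i<=t} M_i / M_initial``; it is non-decreasing by
    construction.  A cumulative value exceeding 100% by more than
    ``over_100_tolerance_pct`` points triggers a :class:`DataQualityWarning`
    (measurement noise can push real data slightly above 100%).
    """
    cum = np.cumsum(series.masses)
    pct_final = 100.0 * cum[-1] / series.m_initial if cum.size else 0.0
    if pct_final > 100.0 + over_100_tolerance_pct:
        warnings.warn(
            f"cumulative release reaches {pct_final:.1f}% of the initial loading "
            f"(> 100% + {over_100_tolerance_pct}% tolerance)",
            DataQualityWarning,
            stacklevel=2,
        )
    return ReleaseCurve(times=series.times, cumulative_mass=cum, m_infinity=series.m_initial)


def r_squared(observed, predicted) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot``.

    ``SS_tot`` is taken about the mean of ``observed``.  Raises
    :class:`UndefinedStatisticError` if ``observed`` is constant.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise InvalidParameterError("observed and predicted must be 1-D and equal length")
    if obs.size < 2:
        raise InvalidParameterError("need at least two points for R^2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedStatisticError("R^2 is undefined for a constant observed series")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot
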