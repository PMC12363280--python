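"""Perfusion-bioreactor data reduction.

Covers the shell of bookkeeping around the flow experiment: calibrating
the peristaltic pump (collected water mass -> volumetric flow -> linear
flow-vs-RPM regression), assembling cumulative release from the
fraction collector's 2-h bins, predicting the dead-volume detection
delay, and checking the end-of-run mass balance across gel
compartments (released + remaining in each gel section ~ 100% of the
loading).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .curves import ReleaseCurve
from .exceptions import (
    DataQualityWarning,
    InsufficientDataError,
    InvalidParameterError,
)

__all__ = [
    "CalibrationRecord",
    "PumpCalibration",
    "FractionSeries",
    "CompartmentDistribution",
    "water_density",
    "flow_from_collection",
    "fit_pump_calibration",
    "cumulative_release_from_fractions",
    "dead_time",
    "mass_balance",
    "WATER_DENSITY_TABLE",
]

# Reference density of air-free water at standard atmosphere, g/mL,
# 0-80 degC at 5 degC spacing (CRC Handbook values).  A degree-4
# polynomial fitted to this table reproduces it to < 1e-4 g/mL and
# stands in for an external thermophysical library.
WATER_DENSITY_TABLE = (
    (0.0, 0.99984), (5.0, 0.99997), (10.0, 0.99970), (15.0, 0.99910),
    (20.0, 0.99820), (25.0, 0.99705), (30.0, 0.99565), (35.0, 0.99403),
    (40.0, 0.99222), (45.0, 0.99022), (50.0, 0.98804), (55.0, 0.98570),
    (60.0, 0.98321), (65.0, 0.98056), (70.0, 0.97778), (75.0, 0.97486),
    (80.0, 0.97180),
)

_DENSITY_POLY_DEGREE = 4
_density_poly = None


def _get_density_poly():
    global _density_poly
    if _density_poly is None:
        t = np.array([row[0] for row in WATER_DENSITY_TABLE])
        rho = np.array([row[1] for row in WATER_DENSITY_TABLE])
        _density_poly = np.polynomial.Polynomial.fit(t, rho, _DENSITY_POLY_DEGREE)
    return _density_poly


def water_density(temperature_c: float) -> float:
    """Density of water (g/mL) at ``temperature_c`` in [0, 80] degC,
    from a degree-4 polynomial fit to the bundled reference table."""
    if not 0.0 <= temperature_c <= 80.0:
        raise InvalidParameterError(
            f"temperature {temperature_c} degC outside the calibrated range [0, 80]"
        )
    return float(_get_density_poly()(temperature_c))


@dataclass(frozen=True)
class CalibrationRecord:
    """One pump-calibration measurement: water mass ``mass_g`` collected
    over ``minutes`` at pump speed ``rpm`` and water temperature
    ``temperature_c``."""

    rpm: float
    mass_g: float
    temperature_c: float
    minutes: float

    def __post_init__(self):
        if not (self.rpm > 0 and self.mass_g > 0 and self.temperature_c > 0
                and self.minutes > 0):
            raise InvalidParameterError(f"all calibration-record fields must be > 0: {self}")


@dataclass(frozen=True)
class PumpCalibration:
    """Linear flow-vs-RPM calibration: ``flow = slope * rpm + intercept``
    (mL/min)."""

    slope: float
    intercept: float
    r_squared: float

    def flow_at(self, rpm: float) -> float:
        return self.slope * rpm + self.intercept

    def rpm_for(self, flow_ml_min: float) -> float:
        return (flow_ml_min - self.intercept) / self.slope


def flow_from_collection(record: CalibrationRecord) -> float:
    """Volumetric flow (mL/min) = collected mass / (density(T) * time)."""
    rho = water_density(record.temperature_c)
    return record.mass_g / (rho * record.minutes)


def fit_pump_calibration(records) -> PumpCalibration:
    """OLS of mean flow on RPM; replicates are averaged per RPM first.

    Requires at least 2 distinct RPM values.  The fit is invariant to
    record order."""
    records = list(records)
    rpms = sorted({r.rpm for r in records})
    if len(rpms) < 2:
        raise InsufficientDataError(
            f"pump calibration needs >= 2 distinct RPM values, got {len(rpms)}"
        )
    mean_flows = np.array(
        [np.mean([flow_from_collection(r) for r in records if r.rpm == rpm]) for rpm in rpms]
    )
    x = np.asarray(rpms, dtype=float)
    slope, intercept = np.polyfit(x, mean_flows, 1)
    pred = slope * x + intercept
    ss_tot = float(np.sum((mean_flows - mean_flows.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - float(np.sum((mean_flows - pred) ** 2)) / ss_tot
    return PumpCalibration(slope=float(slope), intercept=float(intercept), r_squared=r2)


@dataclass(frozen=True)
class FractionSeries:
    """Fraction-collector series: released mass per collection bin.

    ``fraction_masses[i]`` is the mass (µg) in the bin ending at
    ``(i + 1) * interval_h`` hours.  ``flow_rate`` in µL/min,
    ``dead_volume_ul`` is the tubing volume between chamber and
    collector."""

    flow_rate: float
    fraction_masses: np.ndarray
    m_initial: float
    interval_h: float = 2.0
    dead_volume_ul: float = 0.0

    def __post_init__(self):
        m = np.asarray(self.fraction_masses, dtype=float)
        object.__setattr__(self, "fraction_masses", m)
        if np.any(m < 0):
            raise InvalidParameterError("fraction masses must be >= 0")
        if not self.interval_h > 0:
            raise InvalidParameterError("interval_h must be > 0")
        if not self.m_initial > 0:
            raise InvalidParameterError("m_initial must be > 0")
        if not self.flow_rate > 0:
            raise InvalidParameterError("flow_rate must be > 0")
        if self.dead_volume_ul < 0:
            raise InvalidParameterError("dead_volume_ul must be >= 0")

    @property
    def times(self) -> np.ndarray:
        """Right edge of each collection bin, hours."""
        return self.interval_h * np.arange(1, self.fraction_masses.size + 1)


def cumulative_release_from_fractions(
    series: FractionSeries, *, over_100_tolerance_pct: float = 5.0
) -> ReleaseCurve:
    """Cumulative release percent at the end of each collection bin
    (times are bin right-edges)."""
    cum = np.cumsum(series.fraction_masses)
    if cum.size and 100.0 * cum[-1] / series.m_initial > 100.0 + over_100_tolerance_pct:
        warnings.warn(
            f"cumulative release {100.0 * cum[-1] / series.m_initial:.1f}% exceeds "
            "100% beyond tolerance",
            DataQualityWarning,
            stacklevel=2,
        )
    return ReleaseCurve(
        times=series.times, cumulative_mass=cum, m_infinity=series.m_initial
    )


def dead_time(flow_ul_min: float, dead_volume_ul: float, interval_h: float = 2.0) -> float:
    """First bin edge (h) at which released solute can be detected.

    The raw tubing delay is ``dead_volume / flow`` converted to hours;
    detection happens in the collection bin containing that delay, so
    the result is the delay rounded up to the next bin edge (and the
    first bin, ``interval_h``, when the dead volume is zero)."""
    if not flow_ul_min > 0:
        raise InvalidParameterError("flow must be > 0")
    if dead_volume_ul < 0:
        raise InvalidParameterError("dead volume must be >= 0")
    if not interval_h > 0:
        raise InvalidParameterError("interval_h must be > 0")
    raw_h = dead_volume_ul / flow_ul_min / 60.0
    return interval_h * max(1, math.ceil(raw_h / interval_h - 1e-12))


@dataclass(frozen=True)
class CompartmentDistribution:
    """End-of-run distribution of the loading across the system, each
    value a percent of ``m_initial``: mass released to the collector,
    and mass remaining in the downstream Alg:M gel, the central alginate
    gel, the nanoparticles, and the upstream Alg:M gel."""

    released_pct: float
    algM_downflow_pct: float
    alginate_core_pct: float
    np_pct: float
    algM_upflow_pct: float

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if v < 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {v}")

    @property
    def compartments(self) -> tuple:
        return (
            self.algM_downflow_pct,
            self.alginate_core_pct,
            self.np_pct,
            self.algM_upflow_pct,
        )

    def closure(self) -> float:
        return mass_balance(self.released_pct, self.compartments)


def mass_balance(
    released_pct: float,
    compartment_percents,
    *,
    tolerance_pct: float = 5.0,
    flag: bool = True,
) -> float:
    """Sum of released and compartment percentages (the closure).

    A closure outside ``100 +/- tolerance_pct`` on measured data is
    flagged with a :class:`DataQualityWarning`, never an exception;
    synthetic pipelines close at 100 exactly by construction."""
    comp = np.asarray(compartment_percents, dtype=float)
    if released_pct < 0 or np.any(comp < 0):
        raise InvalidParameterError("percentages must be >= 0")
    closure = float(released_pct + comp.sum())
    if flag and abs(closure - 100.0) > tolerance_pct:
        warnings.warn(
            f"mass-balance closure {closure:.2f}% deviates from 100% by more than "
            f"{tolerance_pct} points",
            DataQualityWarning,
            stacklevel=2,
        )
    return closure
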