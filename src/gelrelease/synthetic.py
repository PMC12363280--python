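"""Synthetic release datasets with the statistical structure the
analysis assumes, so the whole pipeline runs without external data.

Static datasets are generated by the forward diffusion model itself:
cumulative release is simulated at the experimental sampling schedule,
differenced into per-interval supernatant masses (the measured
quantity under complete supernatant replacement), and perturbed with
multiplicative Gaussian noise per replicate.  The bundled reference
conditions use the fitted transport parameters of the three hydrogel
systems (alginate 1%, alginate:Matrigel 50:50, and
nanoparticle-in-alginate) at the three loadings (0.4/0.8/1.6 µg/mL),
with the pseudo-equilibrium concentration back-calculated from each
condition's observed release plateau.

Perfusion datasets are phenomenological (no mechanistic flow-transport
model is defined): cumulative release follows a saturating exponential
toward a flow-dependent extent, delayed by the tubing dead volume and
binned into 2-h fractions; the unreleased remainder is distributed
across the four gel compartments so the mass balance closes at 100%
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import SupernatantSeries
from .exceptions import InvalidParameterError
from .pde import (
    DEFAULT_GEOMETRY,
    Discretization,
    HydrogelGeometry,
    TransportParameters,
    solve_release,
)
from .perfusion import CompartmentDistribution, FractionSeries, dead_time

__all__ = [
    "NoiseModel",
    "StaticTruth",
    "SyntheticStaticDataset",
    "SyntheticPerfusionDataset",
    "generate_static",
    "generate_perfusion",
    "reference_schedules",
    "STATIC_SCHEDULE_H",
    "PERFUSION_INTERVAL_H",
    "PERFUSION_DURATION_H",
    "REFERENCE_CONDITIONS",
    "DEFAULT_EXTENTS",
    "UG_PER_ML_TO_SI",
]

UG_PER_ML_TO_SI = 1.0e6  # µg/mL expressed in µg/m^3

#: static sampling schedule, hours (13 points, 0-168 h)
STATIC_SCHEDULE_H = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 24.0, 48.0, 72.0, 120.0, 144.0, 168.0)

#: perfusion fraction-collector binning
PERFUSION_INTERVAL_H = 2.0
PERFUSION_DURATION_H = 120.0

#: asymptotic released fraction by flow rate (µL/min), matching the
#: observed ordering of release with flow
DEFAULT_EXTENTS = {0.5: 0.073, 3.0: 0.587, 6.5: 0.925, 10.0: 0.959}

#: split of the unreleased remainder across gel compartments at full
#: release progress (downstream Alg:M, alginate core, nanoparticles,
#: upstream Alg:M); the default "auto" split interpolates between
#: all-in-core (nothing released, nothing migrated) and this vector as
#: the released fraction grows
FULL_RELEASE_COMPARTMENT_SPLIT = (0.55, 0.20, 0.10, 0.15)
_ALL_IN_CORE = (0.0, 1.0, 0.0, 0.0)

DEFAULT_DEAD_VOLUME_UL = 300.0
DEFAULT_RATE_CONSTANT_PER_H = 0.05


def reference_schedules() -> dict:
    """Named observation schedules: the 13-point static schedule and the
    2-h perfusion bin edges out to 120 h."""
    n_bins = int(round(PERFUSION_DURATION_H / PERFUSION_INTERVAL_H))
    return {
        "static": np.asarray(STATIC_SCHEDULE_H),
        "perfusion": PERFUSION_INTERVAL_H * np.arange(1, n_bins + 1),
    }


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian noise on per-interval released masses:
    ``M_i -> M_i * (1 + N(0, relative_sd))``, truncated at zero when
    ``floor`` is set."""

    relative_sd: float = 0.05
    floor: bool = True

    def __post_init__(self):
        if self.relative_sd < 0:
            raise InvalidParameterError("relative_sd must be >= 0")

    def apply(self, masses: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.relative_sd == 0.0:
            return masses.copy()
        out = masses * (1.0 + rng.normal(0.0, self.relative_sd, size=masses.shape))
        if self.floor:
            out = np.maximum(out, 0.0)
        return out


@dataclass(frozen=True)
class StaticTruth:
    """Generating ground truth for a static condition.

    ``c_eq_fraction`` is C_eq / C_initial (sets the release plateau at
    ``100 (1 - c_eq_fraction)`` percent)."""

    d_eff: float
    k: float
    c_initial_ug_ml: float
    c_eq_fraction: float = 0.0
    geometry: HydrogelGeometry = DEFAULT_GEOMETRY
    label: str = ""

    def __post_init__(self):
        if not 0.0 <= self.c_eq_fraction <= 1.0:
            raise InvalidParameterError("c_eq_fraction must be in [0, 1]")
        if not self.c_initial_ug_ml > 0:
            raise InvalidParameterError("c_initial_ug_ml must be > 0")

    @property
    def c_initial_si(self) -> float:
        return self.c_initial_ug_ml * UG_PER_ML_TO_SI

    @property
    def params(self) -> TransportParameters:
        return TransportParameters(
            d_eff=self.d_eff, k=self.k, c_eq=self.c_eq_fraction * self.c_initial_si
        )


def _truth(label, d_eff, k, c_init, plateau_pct):
    return StaticTruth(
        d_eff=d_eff,
        k=k,
        c_initial_ug_ml=c_init,
        c_eq_fraction=1.0 - plateau_pct / 100.0,
        label=label,
    )


#: fitted transport parameters of the three hydrogel systems at the
#: three loadings, with C_eq back-calculated from each observed plateau
REFERENCE_CONDITIONS = {
    "alginate-0.4": _truth("alginate-0.4", 1.04e-9, 4.13e-5, 0.4, 46.07),
    "alginate-0.8": _truth("alginate-0.8", 1.98e-9, 4.59e-5, 0.8, 50.04),
    "alginate-1.6": _truth("alginate-1.6", 1.40e-9, 1.190e-5, 1.6, 54.31),
    "alg-matrigel-0.4": _truth("alg-matrigel-0.4", 1.2e-9, 6.75e-5, 0.4, 83.52),
    "alg-matrigel-0.8": _truth("alg-matrigel-0.8", 1.1e-9, 4.58e-5, 0.8, 67.07),
    "alg-matrigel-1.6": _truth("alg-matrigel-1.6", 1.4e-9, 2.40e-5, 1.6, 50.59),
    "np-alginate-0.4": _truth("np-alginate-0.4", 2.4e-10, 2.98e-6, 0.4, 21.77),
    "np-alginate-0.8": _truth("np-alginate-0.8", 1.28e-10, 1.28e-6, 0.8, 16.85),
    "np-alginate-1.6": _truth("np-alginate-1.6", 3.91e-10, 3.05e-6, 1.6, 7.75),
}


@dataclass(frozen=True)
class SyntheticStaticDataset:
    truth: StaticTruth
    schedule: np.ndarray
    replicates: list
    seed: int
    noise: NoiseModel = field(default_factory=NoiseModel)

    @property
    def m_initial_ug(self) -> float:
        return self.replicates[0].m_initial


def generate_static(
    truth: StaticTruth,
    schedule=None,
    noise: NoiseModel = NoiseModel(),
    n_replicates: int = 3,
    seed: int = 0,
    disc: Discretization = Discretization(),
) -> SyntheticStaticDataset:
    """Simulate replicate supernatant series for a static condition.

    Per-interval masses are the differences of the forward model's
    cumulative released mass at the schedule times, perturbed per
    replicate with independent noise streams spawned from ``seed``.
    With zero noise the dataset reproduces the forward model exactly.
    """
    if schedule is None:
        schedule = reference_schedules()["static"]
    schedule = np.asarray(schedule, dtype=float)
    if schedule.size < 2 or np.any(np.diff(schedule) <= 0):
        raise InvalidParameterError("schedule must be strictly increasing, length >= 2")
    obs = schedule if schedule[0] > 0 else schedule[1:]
    curve, _ = solve_release(truth.geometry, truth.params, truth.c_initial_si, disc, obs)
    cumulative = np.interp(schedule, obs, curve.cumulative_mass, left=0.0)
    intervals = np.diff(cumulative, prepend=0.0)
    m_initial = truth.c_initial_si * truth.geometry.volume

    streams = np.random.SeedSequence(seed).spawn(n_replicates)
    replicates = [
        SupernatantSeries(
            times=schedule,
            masses=noise.apply(intervals, np.random.default_rng(s)),
            m_initial=m_initial,
        )
        for s in streams
    ]
    return SyntheticStaticDataset(
        truth=truth, schedule=schedule, replicates=replicates, seed=seed, noise=noise
    )


@dataclass(frozen=True)
class SyntheticPerfusionDataset:
    flow_rate: float
    truth_extent: float
    rate_constant: float
    dead_volume_ul: float
    fractions: FractionSeries
    compartments: CompartmentDistribution
    seed: int


def generate_perfusion(
    flow_ul_min: float,
    dead_volume_ul: float = DEFAULT_DEAD_VOLUME_UL,
    extent: float | None = None,
    rate_constant: float = DEFAULT_RATE_CONSTANT_PER_H,
    noise: NoiseModel = NoiseModel(relative_sd=0.0),
    seed: int = 0,
    *,
    m_initial_ug: float = 0.0855,
    interval_h: float = PERFUSION_INTERVAL_H,
    duration_h: float = PERFUSION_DURATION_H,
    compartment_split="auto",
) -> SyntheticPerfusionDataset:
    """Simulate one perfusion run.

    Cumulative release follows ``extent * (1 - exp(-rate * (t - t0)))``
    after the raw dead-volume delay ``t0``; the series is binned into
    fraction masses, noise applied, and the unreleased remainder split
    across the four gel compartments so the closure is exactly 100%.
    ``extent`` defaults to the flow-matched entry of
    :data:`DEFAULT_EXTENTS` (interpolated for other flows).

    With ``compartment_split="auto"`` the residual split interpolates,
    in the released fraction, between everything-still-in-the-core (no
    release implies no migration into the flanking Alg:M gels) and
    :data:`FULL_RELEASE_COMPARTMENT_SPLIT`; pass a 4-tuple of weights
    to override.
    """
    if extent is None:
        flows = np.array(sorted(DEFAULT_EXTENTS))
        extent = float(np.interp(flow_ul_min, flows, [DEFAULT_EXTENTS[f] for f in flows]))
    if not 0.0 <= extent <= 1.0:
        raise InvalidParameterError("extent must be in [0, 1]")
    if rate_constant < 0:
        raise InvalidParameterError("rate_constant must be >= 0")

    n_bins = int(round(duration_h / interval_h))
    edges = interval_h * np.arange(0, n_bins + 1)
    t0 = dead_volume_ul / flow_ul_min / 60.0  # raw delay, hours

    def cum_frac(t):
        t = np.asarray(t, dtype=float)
        return extent * (1.0 - np.exp(-rate_constant * np.maximum(t - t0, 0.0)))

    masses = m_initial_ug * np.diff(cum_frac(edges))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    masses = noise.apply(masses, rng)
    total = masses.sum()
    if total > m_initial_ug:  # noise pushed the sum past the loading
        masses = masses * (m_initial_ug / total)
        total = m_initial_ug

    fractions = FractionSeries(
        flow_rate=flow_ul_min,
        fraction_masses=masses,
        m_initial=m_initial_ug,
        interval_h=interval_h,
        dead_volume_ul=dead_volume_ul,
    )
    if isinstance(compartment_split, str):
        if compartment_split != "auto":
            raise InvalidParameterError(f"unknown compartment_split {compartment_split!r}")
        r = total / m_initial_ug
        split = (1.0 - r) * np.asarray(_ALL_IN_CORE) + r * np.asarray(
            FULL_RELEASE_COMPARTMENT_SPLIT
        )
    else:
        split = np.asarray(compartment_split, dtype=float)
    if split.size != 4 or np.any(split < 0) or split.sum() <= 0:
        raise InvalidParameterError("compartment_split must be 4 non-negative weights")
    split = split / split.sum()
    residual_pct = 100.0 * (m_initial_ug - total) / m_initial_ug
    released_pct = 100.0 * total / m_initial_ug
    compartments = CompartmentDistribution(
        released_pct=released_pct,
        algM_downflow_pct=residual_pct * split[0],
        alginate_core_pct=residual_pct * split[1],
        np_pct=residual_pct * split[2],
        algM_upflow_pct=residual_pct * split[3],
    )
    return SyntheticPerfusionDataset(
        flow_rate=flow_ul_min,
        truth_extent=extent,
        rate_constant=rate_constant,
        dead_volume_ul=dead_volume_ul,
        fractions=fractions,
        compartments=compartments,
        seed=seed,
    )
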