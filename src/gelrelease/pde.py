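"""Forward model: 1-D axial Fickian release from a cylindrical hydrogel.

Model
-----
The gel is a cylinder of radius ``R`` and height ``L``.  Transport is
modelled as one-dimensional diffusion along the axis ``z`` (isotropic in
the axial dimension, null in the radial dimension), so the cylinder acts
as a slab of thickness ``L`` whose radius enters only through the
cross-sectional area ``pi R^2`` in the mass balance:

    dC/dt = D_eff d2C/dz2,        z in [0, L]

with a uniform initial concentration ``C(z, 0) = C_initial``, a sealed
base (``dC/dz = 0`` at ``z = 0``) and an interaction-limited release
surface at ``z = L`` written in flux form,

    -D_eff dC/dz|_L = k (C|_L - C_eq),

where ``k`` (m/s) is the overall surface mass-transfer coefficient and
``C_eq`` the pseudo-equilibrium concentration at which net release
stops (attributed to electrostatic solute/alginate interactions; it sets
the sub-100% plateau).  The released mass is

    M_t = M_inf - pi R^2 * integral_0^L C dz   (trapezoidal rule),

with ``M_inf = C_initial * pi R^2 L``.

Numerics
--------
Crank-Nicolson in time with second-order ghost-node boundary closures
and a tridiagonal solve per step.  The uniform initial state is
incompatible with the Robin surface condition, which makes the early
solution behave like sqrt(t); plain Crank-Nicolson then produces large
oscillations (including strongly negative surface values) at coarse
time steps.  The first macro step is therefore integrated with a ramp
of geometrically graded, damped (backward-Euler) sub-steps that resolve
the startup singularity; subsequent steps are pure Crank-Nicolson.
This preserves second-order convergence in space and time.

Units: geometry in m, time arguments at the API boundary in hours,
``dt`` in seconds; concentrations in any fixed unit per m^3, masses in
that same unit (the PDE is linear, so the unit cancels everywhere
except in absolute masses).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded
from scipy.optimize import brentq

from .curves import ReleaseCurve
from .exceptions import AccuracyWarning, InvalidParameterError, MassBalanceError

__all__ = [
    "HydrogelGeometry",
    "TransportParameters",
    "Discretization",
    "ConcentrationProfile",
    "solve_release",
    "crank_nicolson_step",
    "cumulative_mass",
    "loaded_mass",
    "analytic_release_fraction",
    "plateau_percent",
]

#: number of geometrically graded damped sub-steps covering the first macro step
N_STARTUP_SUBSTEPS = 16
#: dimensionless time step D*dt/L^2 above which an accuracy warning is
#: raised (fewer than ~40 steps per diffusion time under-resolves the
#: release transient and lets slowly decaying oscillatory CN modes
#: surface at late times)
ACCURACY_STEP_BOUND = 0.025
#: relative tolerance below which a negative concentration is considered a solver bug
NEGATIVITY_TOL = 1e-12

SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class HydrogelGeometry:
    """Cylindrical gel geometry: ``radius`` and ``height`` (axial extent L), in m."""

    radius: float
    height: float

    def __post_init__(self):
        if not (self.radius > 0 and self.height > 0):
            raise InvalidParameterError(
                f"radius and height must be > 0, got {self.radius}, {self.height}"
            )

    @property
    def cross_section(self) -> float:
        """Cross-sectional area pi R^2 (m^2)."""
        return math.pi * self.radius**2

    @property
    def volume(self) -> float:
        return self.cross_section * self.height


#: default geometry: 6.5 mm diameter, 5 mm height
DEFAULT_GEOMETRY = HydrogelGeometry(radius=3.25e-3, height=5.0e-3)


@dataclass(frozen=True)
class TransportParameters:
    """Transport unknowns of the release model.

    d_eff : effective diffusivity (m^2/s), > 0
    k : overall surface mass-transfer coefficient (m/s), >= 0
    c_eq : pseudo-equilibrium concentration (same unit as the field), >= 0
    """

    d_eff: float
    k: float
    c_eq: float = 0.0

    def __post_init__(self):
        if not self.d_eff > 0:
            raise InvalidParameterError(f"d_eff must be > 0, got {self.d_eff}")
        if self.k < 0:
            raise InvalidParameterError(f"k must be >= 0, got {self.k}")
        if self.c_eq < 0:
            raise InvalidParameterError(f"c_eq must be >= 0, got {self.c_eq}")

    def biot(self, geometry: HydrogelGeometry) -> float:
        """Biot number ``k L / D_eff`` (surface vs internal conductance)."""
        return self.k * geometry.height / self.d_eff


@dataclass(frozen=True)
class Discretization:
    """Spatial/temporal grid: ``n_nodes`` nodes over [0, L] (dz = L/(n_nodes-1))
    and time step ``dt`` in seconds.  Defaults: 31 nodes (dz = L/30) and 300 s."""

    n_nodes: int = 31
    dt: float = 300.0

    def __post_init__(self):
        if self.n_nodes < 3:
            raise InvalidParameterError(f"n_nodes must be >= 3, got {self.n_nodes}")
        if not self.dt > 0:
            raise InvalidParameterError(f"dt must be > 0, got {self.dt}")

    def dz(self, geometry: HydrogelGeometry) -> float:
        return geometry.height / (self.n_nodes - 1)


@dataclass(frozen=True)
class ConcentrationProfile:
    """Axial concentration field ``c(z)`` at simulation time ``t`` (s).

    ``z`` runs from 0 (sealed base) to L (release surface)."""

    z: np.ndarray
    c: np.ndarray
    t: float

    def __post_init__(self):
        z = np.asarray(self.z, dtype=float)
        c = np.asarray(self.c, dtype=float)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "c", c)
        if z.ndim != 1 or c.shape != z.shape:
            raise InvalidParameterError("z and c must be 1-D and equal length")
        if np.any(np.diff(z) <= 0):
            raise InvalidParameterError("z must be strictly increasing")


def _theta_matrices(params, geometry, n_nodes, dt, theta):
    """LHS banded matrix A, RHS banded matrix B and constant d for one
    theta-scheme step with ghost-node Neumann (base) / Robin (surface)
    closures: ``A c_new = B c_old + d``."""
    dz = geometry.height / (n_nodes - 1)
    s = params.d_eff * dt / dz**2
    beta = 2.0 * dz * params.k / params.d_eff

    def banded(coef):
        # coef multiplies the discrete Laplacian contribution
        ab = np.zeros((3, n_nodes))
        ab[1, :] = 1.0 + 2.0 * coef * s
        ab[1, -1] = 1.0 + coef * s * (2.0 + beta)
        ab[0, 1:] = -coef * s  # superdiagonal
        ab[0, 1] = -2.0 * coef * s  # base ghost node
        ab[2, :-1] = -coef * s  # subdiagonal
        ab[2, -2] = -2.0 * coef * s  # surface ghost node
        return ab

    A = banded(theta)
    B = banded(-(1.0 - theta))  # sign flip: RHS terms add, not subtract
    d = np.zeros(n_nodes)
    d[-1] = s * beta * params.c_eq
    return A, B, d


def _apply_banded(ab, c):
    """Tridiagonal matrix-vector product for the 3-row banded storage."""
    out = ab[1] * c
    out[:-1] += ab[0, 1:] * c[1:]
    out[1:] += ab[2, :-1] * c[:-1]
    return out


def crank_nicolson_step(
    profile: ConcentrationProfile,
    params: TransportParameters,
    geometry: HydrogelGeometry,
    disc: Discretization,
) -> ConcentrationProfile:
    """Advance the concentration profile by one plain Crank-Nicolson step.

    Interior nodes use the theta = 1/2 average of explicit and implicit
    second differences; boundary rows encode the ghost-node forms of the
    sealed-base Neumann and surface Robin conditions.  One tridiagonal
    solve per call.
    """
    if profile.c.size != disc.n_nodes:
        raise InvalidParameterError(
            f"profile has {profile.c.size} nodes, discretization expects {disc.n_nodes}"
        )
    A, B, d = _theta_matrices(params, geometry, disc.n_nodes, disc.dt, theta=0.5)
    rhs = _apply_banded(B, profile.c) + d
    c_new = solve_banded((1, 1), A, rhs)
    return ConcentrationProfile(z=profile.z, c=c_new, t=profile.t + disc.dt)


def _trapezoid_weights(n_nodes, dz):
    w = np.full(n_nodes, dz)
    w[0] = w[-1] = dz / 2.0
    return w


def loaded_mass(geometry: HydrogelGeometry, c_initial: float) -> float:
    """Initial loading ``M_inf = C_initial * pi R^2 L`` (mass unit of c)."""
    return c_initial * geometry.volume


def cumulative_mass(
    profile: ConcentrationProfile, geometry: HydrogelGeometry, m_infinity: float
) -> float:
    """Released mass ``M_t = M_inf - pi R^2 * trapz(c, z)``.

    Raises :class:`MassBalanceError` if the result is negative beyond
    numerical tolerance (which signals a solver bug, since the profile
    integral can never exceed the loading for a valid solution).
    """
    remaining = geometry.cross_section * float(np.trapezoid(profile.c, profile.z))
    m_t = m_infinity - remaining
    if m_t < -1e-9 * m_infinity:
        raise MassBalanceError(
            f"released mass {m_t:.3e} is negative beyond tolerance (M_inf={m_infinity:.3e})"
        )
    return m_t


def solve_release(
    geometry: HydrogelGeometry,
    params: TransportParameters,
    c_initial: float,
    disc: Discretization = Discretization(),
    obs_times: "np.ndarray | list[float]" = (),
    *,
    track_flux: bool = False,
) -> tuple[ReleaseCurve, list[ConcentrationProfile]]:
    """Simulate release and report it at the requested observation times.

    Parameters
    ----------
    c_initial : float
        Uniform initial concentration (same unit as ``params.c_eq``,
        per m^3); masses come out in that unit.
    obs_times : array-like of float
        Observation times in **hours**, sorted, >= 0.  Released mass at
        each time is obtained by linear interpolation between
        integration steps; the concentration profile at each time is
        interpolated the same way.
    track_flux : bool
        If True, attach solver diagnostics to the returned curve:
        per-step times (s), profile-integral released mass and the
        time-integrated Robin boundary flux (same mass unit), for
        mass-balance verification.

    Returns
    -------
    (ReleaseCurve, list of ConcentrationProfile)
    """
    obs = np.asarray(obs_times, dtype=float)
    if obs.ndim != 1:
        raise InvalidParameterError("obs_times must be one-dimensional")
    if obs.size == 0:
        raise InvalidParameterError("obs_times must contain at least one time")
    if np.any(obs < 0) or np.any(np.diff(obs) < 0):
        raise InvalidParameterError("obs_times must be sorted and >= 0")
    if c_initial < 0:
        raise InvalidParameterError("c_initial must be >= 0")

    n = disc.n_nodes
    dz = disc.dz(geometry)
    dt = disc.dt
    dimless_step = params.d_eff * dt / geometry.height**2
    if dimless_step > ACCURACY_STEP_BOUND:
        warnings.warn(
            f"dimensionless time step D*dt/L^2 = {dimless_step:.3g} exceeds the "
            f"documented accuracy bound {ACCURACY_STEP_BOUND}; the scheme stays "
            "stable but temporal accuracy degrades",
            AccuracyWarning,
            stacklevel=2,
        )

    z = np.linspace(0.0, geometry.height, n)
    w = _trapezoid_weights(n, dz)
    area = geometry.cross_section
    m_inf = loaded_mass(geometry, c_initial)
    c_scale = max(c_initial, params.c_eq, 1.0e-300)

    t_end_s = float(obs[-1]) * SECONDS_PER_HOUR
    n_macro = max(1, math.ceil(t_end_s / dt - 1e-9))

    # --- time grid: startup sub-steps over (0, dt], then macro CN steps ---
    ratios = 2.0 ** np.arange(N_STARTUP_SUBSTEPS)
    sub_dts = dt * ratios / ratios.sum()
    grid_t = np.concatenate([[0.0], np.cumsum(sub_dts), (np.arange(2, n_macro + 1)) * dt])
    n_grid = grid_t.size

    c = np.full(n, float(c_initial))
    remaining = np.empty(n_grid)
    flux_int = np.empty(n_grid) if track_flux else None
    remaining[0] = w @ c
    if track_flux:
        flux_int[0] = 0.0
        prev_surf = c[-1]

    # which grid indices bracket the observation times (for profiles)
    obs_s = obs * SECONDS_PER_HOUR
    lo_idx = np.clip(np.searchsorted(grid_t, obs_s, side="right") - 1, 0, n_grid - 1)
    hi_idx = np.clip(np.searchsorted(grid_t, obs_s, side="left"), 0, n_grid - 1)
    needed = {0: c.copy()}
    wanted = set(lo_idx.tolist()) | set(hi_idx.tolist())

    def record(i, c, theta):
        remaining[i] = w @ c
        cmin = c.min()
        if cmin < -NEGATIVITY_TOL * c_scale:
            raise MassBalanceError(
                f"negative concentration {cmin:.3e} at t={grid_t[i]:.0f} s "
                "(beyond 1e-12 * c_initial): solver inconsistency"
            )
        if track_flux:
            # Robin flux with the scheme's own theta-weighted surface value;
            # this quadrature makes the discrete balance exact
            nonlocal prev_surf
            surf = theta * c[-1] + (1.0 - theta) * prev_surf
            flux_int[i] = flux_int[i - 1] + params.k * (surf - params.c_eq) * area * (
                grid_t[i] - grid_t[i - 1]
            )
            prev_surf = c[-1]
        if i in wanted:
            needed[i] = c.copy()

    # damped (backward-Euler) geometric startup ramp
    for j, h in enumerate(sub_dts, start=1):
        A, B, d = _theta_matrices(params, geometry, n, h, theta=1.0)
        c = solve_banded((1, 1), A, _apply_banded(B, c) + d)
        record(j, c, 1.0)

    # pure Crank-Nicolson macro steps via the dense one-step propagator
    if n_macro > 1:
        A, B, d = _theta_matrices(params, geometry, n, dt, theta=0.5)
        A_dense = np.diag(A[1]) + np.diag(A[0, 1:], 1) + np.diag(A[2, :-1], -1)
        B_dense = np.diag(B[1]) + np.diag(B[0, 1:], 1) + np.diag(B[2, :-1], -1)
        A_inv = np.linalg.inv(A_dense)
        M = A_inv @ B_dense
        b = A_inv @ d
        base = N_STARTUP_SUBSTEPS
        for step in range(2, n_macro + 1):
            c = M @ c + b
            record(base + step - 1, c, 0.5)

    released_grid = (remaining[0] - remaining) * area
    released_obs = np.interp(obs_s, grid_t, released_grid)

    diagnostics = None
    if track_flux:
        diagnostics = {
            "step_times_s": grid_t,
            "released_profile_integral": released_grid,
            "released_flux_integral": flux_int,
        }
    curve = ReleaseCurve(
        times=obs,
        cumulative_mass=released_obs,
        m_infinity=m_inf if m_inf > 0 else 1.0,
        diagnostics=diagnostics,
    )

    profiles = []
    for t_s, i0, i1 in zip(obs_s, lo_idx, hi_idx):
        c0, c1 = needed[int(i0)], needed[int(i1)]
        if i1 == i0:
            ci = c0
        else:
            frac = (t_s - grid_t[i0]) / (grid_t[i1] - grid_t[i0])
            ci = (1.0 - frac) * c0 + frac * c1
        profiles.append(ConcentrationProfile(z=z, c=ci, t=float(t_s)))
    return curve, profiles


# ---------------------------------------------------------------------------
# analytic oracle: separation-of-variables series for the slab
# ---------------------------------------------------------------------------


def _robin_eigenvalues(biot: float, n_terms: int) -> np.ndarray:
    """First ``n_terms`` roots of ``lam * tan(lam) = Bi`` (one per branch
    ``((i-1) pi, (i-1) pi + pi/2)``)."""
    lam = np.empty(n_terms)
    for i in range(n_terms):
        a = i * np.pi + 1e-12
        b = i * np.pi + np.pi / 2 - 1e-12
        lam[i] = brentq(lambda x: x * np.sin(x) - biot * np.cos(x), a, b)
    return lam


def analytic_release_fraction(
    params: TransportParameters,
    geometry: HydrogelGeometry,
    c_initial: float,
    t: float,
    *,
    tol: float = 1e-12,
    max_terms: int = 5000,
) -> float:
    """Eigenfunction-series released fraction for the slab model.

    Returns ``M_t / (M_inf - pi R^2 L C_eq)``, the fraction of the
    releasable mass, at time ``t`` (hours):

        1 - sum_n [4 sin(lam_n) / (2 lam_n + sin 2 lam_n)]
                  * (sin lam_n / lam_n) * exp(-lam_n^2 D t / L^2)

    with ``lam_n tan lam_n = Bi = k L / D``.  Independent of
    ``c_initial`` (uniform initial state); the argument is kept for
    interface symmetry with :func:`solve_release` and validated.
    Monotone non-decreasing in ``t``.
    """
    if not params.k > 0:
        raise InvalidParameterError("analytic series requires k > 0")
    if t < 0:
        raise InvalidParameterError("t must be >= 0")
    if c_initial < 0:
        raise InvalidParameterError("c_initial must be >= 0")
    if t == 0.0:
        return 0.0
    biot = params.biot(geometry)
    fo = params.d_eff * t * SECONDS_PER_HOUR / geometry.height**2
    # retain modes until exp(-lam^2 Fo) is negligible
    lam_max = math.sqrt(max(-math.log(tol), 1.0) / fo)
    n_terms = min(max_terms, max(8, int(lam_max / math.pi) + 2))
    lam = _robin_eigenvalues(biot, n_terms)
    coef = 4.0 * np.sin(lam) / (2.0 * lam + np.sin(2.0 * lam))
    terms = coef * np.sin(lam) / lam * np.exp(-(lam**2) * fo)
    if n_terms == max_terms and abs(terms[-1]) > tol:
        warnings.warn(
            f"series truncated at {max_terms} terms with last term "
            f"{terms[-1]:.2e} > tol={tol:.0e}",
            AccuracyWarning,
            stacklevel=2,
        )
    return float(1.0 - terms.sum())


def plateau_percent(params: TransportParameters, c_initial: float) -> float:
    """Long-time cumulative release percentage, ``100 (1 - C_eq / C_initial)``.

    This is the t -> infinity limit of the PDE model's cumulative
    percent whenever ``k > 0``: the gel equilibrates uniformly at
    ``C_eq``."""
    if not c_initial > 0:
        raise InvalidParameterError("c_initial must be > 0")
    return 100.0 * (1.0 - params.c_eq / c_initial)
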