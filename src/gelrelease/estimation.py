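"""Inverse problem: transport-parameter estimation by a real-coded GA.

The unknowns of the release model (``d_eff``, ``k`` and optionally
``c_eq``) are estimated from a cumulative release curve by minimizing
the sum of squared differences between observed and modelled cumulative
release *percent* at the observation times.  The search runs in log10
parameter space (the parameters span decades), with tournament
selection, blend (BLX-alpha) crossover, Gaussian mutation and one-elite
preservation, optionally followed by a derivative-free Nelder-Mead
polish from the GA best.  Everything is deterministic given the seed.

The objective is smooth but anisotropic: at high Biot number
(``k L / D_eff >> 1``) the release curve is insensitive to ``k`` and the
``k`` direction of the objective is nearly flat.  Use
:func:`profile_objective` to diagnose this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .curves import ReleaseCurve, r_squared
from .exceptions import (
    EstimationFailureError,
    IdentifiabilityWarning,
    InvalidParameterError,
)
from .pde import Discretization, HydrogelGeometry, TransportParameters, solve_release

__all__ = [
    "GAConfig",
    "FitResult",
    "objective",
    "estimate",
    "profile_objective",
    "DEFAULT_LOG10_BOUNDS",
]

PARAM_NAMES = ("d_eff", "k", "c_eq")

#: default per-parameter search bounds, log10 of SI values; they bracket
#: plausible hydrogel values with about two decades of margin.  The c_eq
#: bounds are relative to c_initial and resolved at fit time.
DEFAULT_LOG10_BOUNDS = {
    "d_eff": (-12.0, -8.0),
    "k": (-8.0, -3.0),
    "c_eq": (-3.0, 0.0),  # log10(c_eq / c_initial)
}

#: objective value assigned when the forward solver fails for a candidate
PENALTY_OBJECTIVE = 1.0e12

#: RMS misfit change (percentage points of release) below which an
#: objective profile is declared flat (weakly identified direction)
FLATNESS_RMS_PCT = 0.5


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings.

    ``bounds`` maps parameter names to (low, high) in log10 space;
    missing entries fall back to :data:`DEFAULT_LOG10_BOUNDS` (for
    ``c_eq`` the default is interpreted relative to ``c_initial``).
    ``polish`` runs a Nelder-Mead refinement from the GA best.  The run
    stops early once the best objective has not improved (relative
    1e-9) for ``stagnation_patience`` generations.
    """

    population_size: int = 60
    generations: int = 80
    crossover_rate: float = 0.9
    mutation_rate: float = 0.15
    bounds: dict = field(default_factory=dict)
    seed: int = 0
    polish: bool = True
    tournament_size: int = 3
    blend_alpha: float = 0.5
    mutation_sigma_frac: float = 0.1
    elitism: int = 1
    stagnation_patience: int = 20

    def __post_init__(self):
        if self.population_size < 10:
            raise InvalidParameterError("population_size must be >= 10")
        if self.generations < 1:
            raise InvalidParameterError("generations must be >= 1")
        for name, rate in (("crossover_rate", self.crossover_rate),
                           ("mutation_rate", self.mutation_rate)):
            if not 0.0 <= rate <= 1.0:
                raise InvalidParameterError(f"{name} must be in [0, 1], got {rate}")
        for key, (lo, hi) in self.bounds.items():
            if key not in PARAM_NAMES:
                raise InvalidParameterError(f"unknown parameter in bounds: {key!r}")
            if not lo <= hi:
                raise InvalidParameterError(f"bounds for {key!r} must satisfy low <= high")


@dataclass(frozen=True)
class FitResult:
    """Outcome of :func:`estimate`."""

    params: TransportParameters
    sse: float
    r_squared: float
    n_evaluations: int
    converged: bool
    seed: int
    free: tuple
    best_per_generation: np.ndarray = field(compare=False, repr=False, default=None)


def objective(
    params: TransportParameters,
    curve: ReleaseCurve,
    geometry: HydrogelGeometry,
    disc: Discretization,
    c_initial: float,
) -> float:
    """Sum of squared differences between observed and modelled
    cumulative release percent at the curve's observation times.

    A forward-solver failure is penalized with a large finite value so
    the search can continue past invalid candidates.
    """
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model_curve, _ = solve_release(geometry, params, c_initial, disc, curve.times)
    except Exception:  # noqa: BLE001 - any solver failure is a penalty
        return PENALTY_OBJECTIVE
    resid = curve.cumulative_percent - model_curve.cumulative_percent
    return float(np.dot(resid, resid))


def _resolve_bounds(free, config, c_initial):
    bounds = []
    for name in free:
        if name in config.bounds:
            lo, hi = config.bounds[name]
        else:
            lo, hi = DEFAULT_LOG10_BOUNDS[name]
            if name == "c_eq":
                lo, hi = lo + np.log10(c_initial), hi + np.log10(c_initial)
        bounds.append((float(lo), float(hi)))
    return np.array(bounds)


def _make_params(genes, free, fixed):
    values = dict(fixed)
    for name, g in zip(free, genes):
        values[name] = 10.0**g
    return TransportParameters(**values)


def estimate(
    curve: ReleaseCurve,
    geometry: HydrogelGeometry,
    disc: Discretization,
    c_initial: float,
    free_params: tuple = ("d_eff", "k", "c_eq"),
    config: GAConfig | None = None,
    *,
    fixed: dict | None = None,
) -> FitResult:
    """Estimate transport parameters from a cumulative release curve.

    Parameters
    ----------
    free_params : subset of {'d_eff', 'k', 'c_eq'}
        Parameters searched by the GA (in log10 space).  By default all
        three are estimated jointly: a release plateau below 100%
        cannot be reproduced without a nonzero ``c_eq``.
    fixed : dict
        Values for the parameters not being searched; ``c_eq`` defaults
        to 0 if neither free nor fixed.

    Returns the best parameters found; with ``config.polish`` a
    Nelder-Mead simplex refines the GA best.  ``r_squared`` is computed
    from a final forward solve at the returned parameters.
    """
    config = config or GAConfig()
    free = tuple(free_params)
    if not free or any(p not in PARAM_NAMES for p in free):
        raise InvalidParameterError(f"free_params must be a non-empty subset of {PARAM_NAMES}")
    if len(curve) < 4:
        raise InvalidParameterError("need at least 4 observation points to fit")
    fixed = dict(fixed or {})
    for name in PARAM_NAMES:
        if name not in free and name not in fixed:
            if name == "c_eq":
                fixed[name] = 0.0
            else:
                raise InvalidParameterError(f"parameter {name!r} is neither free nor fixed")

    bounds = _resolve_bounds(free, config, c_initial)
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    rng = np.random.default_rng(config.seed)
    n_genes = len(free)
    n_eval = 0

    def evaluate(genes):
        nonlocal n_eval
        n_eval += 1
        try:
            p = _make_params(genes, free, fixed)
        except InvalidParameterError:
            return PENALTY_OBJECTIVE
        return objective(p, curve, geometry, disc, c_initial)

    pop = rng.uniform(lo, hi, size=(config.population_size, n_genes))
    fitness = np.array([evaluate(ind) for ind in pop])
    if np.all(fitness >= PENALTY_OBJECTIVE):
        raise EstimationFailureError(
            "every individual of the initial population failed the forward solve; "
            f"bounds={bounds.tolist()}, free={free}"
        )

    best_hist = []
    stagnant = 0
    converged = False
    for _ in range(config.generations):
        order = np.argsort(fitness)
        elite = pop[order[: config.elitism]].copy()
        new_pop = [e for e in elite]
        while len(new_pop) < config.population_size:
            parents = []
            for _ in range(2):
                idx = rng.integers(0, config.population_size, size=config.tournament_size)
                parents.append(pop[idx[np.argmin(fitness[idx])]])
            p1, p2 = parents
            if rng.random() < config.crossover_rate:
                # BLX-alpha: sample each gene uniformly in the blended interval
                a = config.blend_alpha
                gmin = np.minimum(p1, p2) - a * np.abs(p1 - p2)
                gmax = np.maximum(p1, p2) + a * np.abs(p1 - p2)
                child = rng.uniform(gmin, gmax)
            else:
                child = p1.copy()
            mutate = rng.random(n_genes) < config.mutation_rate
            child = child + mutate * rng.normal(0.0, config.mutation_sigma_frac * span)
            new_pop.append(np.clip(child, lo, hi))
        pop = np.asarray(new_pop)
        fitness = np.concatenate(
            [fitness[order[: config.elitism]],
             [evaluate(ind) for ind in pop[config.elitism:]]]
        )
        best = float(fitness.min())
        if best_hist and best >= best_hist[-1] * (1.0 - 1e-9):
            stagnant += 1
        else:
            stagnant = 0
        best_hist.append(min(best, best_hist[-1]) if best_hist else best)
        if stagnant >= config.stagnation_patience:
            converged = True
            break

    best_genes = pop[int(np.argmin(fitness))]

    if config.polish:
        res = minimize(
            evaluate,
            best_genes,
            method="Nelder-Mead",
            bounds=[(l, h) for l, h in bounds],
            options={"fatol": 1e-10, "xatol": 1e-10, "maxfev": 4000},
        )
        if res.fun <= evaluate(best_genes):
            best_genes = np.asarray(res.x)

    best_params = _make_params(best_genes, free, fixed)
    sse = objective(best_params, curve, geometry, disc, c_initial)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model_curve, _ = solve_release(geometry, best_params, c_initial, disc, curve.times)
    try:
        r2 = r_squared(curve.cumulative_percent, model_curve.cumulative_percent)
    except Exception:  # constant observed curve
        r2 = float("nan")
    return FitResult(
        params=best_params,
        sse=float(sse),
        r_squared=float(r2),
        n_evaluations=n_eval,
        converged=converged,
        seed=config.seed,
        free=free,
        best_per_generation=np.asarray(best_hist),
    )


def profile_objective(
    curve: ReleaseCurve,
    geometry: HydrogelGeometry,
    disc: Discretization,
    c_initial: float,
    param_name: str,
    grid,
    at: TransportParameters,
) -> np.ndarray:
    """Objective evaluated along one parameter, others held at ``at``.

    ``grid`` is in natural (not log) units.  If the root-mean-square
    misfit change across the whole grid stays below
    ``FLATNESS_RMS_PCT`` percentage points, the direction is declared
    weakly identified and an :class:`IdentifiabilityWarning` is emitted
    (typical for ``k`` at high Biot number).
    """
    if param_name not in PARAM_NAMES:
        raise InvalidParameterError(f"unknown parameter {param_name!r}")
    grid = np.asarray(grid, dtype=float)
    values = np.empty(grid.size)
    for i, g in enumerate(grid):
        p = replace(at, **{param_name: float(g)})
        values[i] = objective(p, curve, geometry, disc, c_initial)
    n_obs = max(len(curve), 1)
    rms_change = np.sqrt((values.max() - values.min()) / n_obs)
    if rms_change < FLATNESS_RMS_PCT:
        warnings.warn(
            f"objective is nearly flat along {param_name!r}: RMS misfit change "
            f"{rms_change:.3g} percentage points over the grid "
            f"(< {FLATNESS_RMS_PCT}); the parameter is weakly identified",
            IdentifiabilityWarning,
            stacklevel=2,
        )
    return values
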