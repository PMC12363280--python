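"""Model/Results front-end for the release-kinetics analyses.

Two fitted models are exposed in the statsmodels idiom — construct the
model from data, call ``fit()``, inspect the returned results object:

* :class:`FickianReleaseModel` — the mechanistic diffusion model with a
  Robin release surface, fitted by the genetic algorithm.
* :class:`KorsmeyerPeppas` — the empirical early-window power law,
  fitted by log-log regression (per replicate when several curves are
  given).

Concentrations at this layer are in µg/mL and masses in µg; the SI
conversion (1 µg/mL = 1e6 µg/m^3) happens here, once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import ReleaseCurve
from .estimation import FitResult, GAConfig, estimate
from .exceptions import InvalidParameterError
from .kinetics import DEFAULT_WINDOW_H, KPFit, fit_korsmeyer_peppas
from .pde import (
    DEFAULT_GEOMETRY,
    Discretization,
    HydrogelGeometry,
    TransportParameters,
    plateau_percent,
    solve_release,
)

__all__ = [
    "FickianReleaseModel",
    "FickianReleaseResults",
    "KorsmeyerPeppas",
    "KorsmeyerPeppasResults",
    "UG_PER_ML_TO_SI",
]

#: µg/mL expressed per m^3 (so masses computed against m-based geometry are µg)
UG_PER_ML_TO_SI = 1.0e6


class FickianReleaseModel:
    """Axial-diffusion release model with an interaction-limited surface.

    Parameters
    ----------
    curve : ReleaseCurve
        Observed cumulative release (times in h, masses in µg).
    c_initial : float
        Initial loading concentration in µg/mL.
    geometry, disc : optional
        Gel geometry and solver grid; defaults are the 6.5 mm x 5 mm
        cylinder with 31 nodes and a 300 s step.
    """

    def __init__(
        self,
        curve: ReleaseCurve,
        c_initial: float,
        geometry: HydrogelGeometry = DEFAULT_GEOMETRY,
        disc: Discretization = Discretization(),
    ):
        if not c_initial > 0:
            raise InvalidParameterError("c_initial must be > 0 (µg/mL)")
        self.curve = curve
        self.c_initial = float(c_initial)
        self.geometry = geometry
        self.disc = disc

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        c_initial: float,
        m_infinity: float | None = None,
        **kwargs,
    ) -> "FickianReleaseModel":
        """Build from a DataFrame with ``time_h`` and either
        ``cumulative_percent`` or ``cumulative_mass_ug`` columns."""
        if "time_h" not in data.columns:
            raise InvalidParameterError("data must have a 'time_h' column")
        t = data["time_h"].to_numpy(dtype=float)
        if "cumulative_percent" in data.columns:
            if m_infinity is None:
                m_infinity = 1.0  # percent-only data: mass scale is arbitrary
            mass = data["cumulative_percent"].to_numpy(dtype=float) / 100.0 * m_infinity
        elif "cumulative_mass_ug" in data.columns:
            if m_infinity is None:
                raise InvalidParameterError("m_infinity (µg) required with mass data")
            mass = data["cumulative_mass_ug"].to_numpy(dtype=float)
        else:
            raise InvalidParameterError(
                "data must have 'cumulative_percent' or 'cumulative_mass_ug'"
            )
        curve = ReleaseCurve(times=t, cumulative_mass=mass, m_infinity=float(m_infinity))
        return cls(curve, c_initial, **kwargs)

    @property
    def _c_initial_si(self) -> float:
        return self.c_initial * UG_PER_ML_TO_SI

    def fit(
        self,
        free_params: tuple = ("d_eff", "k", "c_eq"),
        config: GAConfig | None = None,
        *,
        fixed: dict | None = None,
    ) -> "FickianReleaseResults":
        """Estimate the free transport parameters by GA + polish.

        ``fixed`` values are in SI (m^2/s, m/s) except ``c_eq`` which is
        in µg/mL like ``c_initial``."""
        fixed_si = dict(fixed or {})
        if "c_eq" in fixed_si:
            fixed_si["c_eq"] = fixed_si["c_eq"] * UG_PER_ML_TO_SI
        result = estimate(
            self.curve,
            self.geometry,
            self.disc,
            self._c_initial_si,
            free_params=free_params,
            config=config,
            fixed=fixed_si,
        )
        return FickianReleaseResults(self, result)

    def simulate(self, params: TransportParameters, times_h) -> ReleaseCurve:
        """Forward-simulate cumulative release (µg / percent) at ``times_h``
        for given parameters (``c_eq`` in SI, i.e. µg/m^3)."""
        curve, _ = solve_release(
            self.geometry, params, self._c_initial_si, self.disc, np.asarray(times_h, float)
        )
        return curve


@dataclass
class FickianReleaseResults:
    """Fitted transport parameters with fit diagnostics.

    ``params`` holds SI values; ``c_eq_ug_ml`` converts the equilibrium
    concentration back to µg/mL."""

    model: FickianReleaseModel
    fit_result: FitResult

    @property
    def params(self) -> TransportParameters:
        return self.fit_result.params

    @property
    def d_eff(self) -> float:
        return self.params.d_eff

    @property
    def k(self) -> float:
        return self.params.k

    @property
    def c_eq_ug_ml(self) -> float:
        return self.params.c_eq / UG_PER_ML_TO_SI

    @property
    def sse(self) -> float:
        return self.fit_result.sse

    @property
    def rsquared(self) -> float:
        return self.fit_result.r_squared

    @property
    def biot(self) -> float:
        return self.params.biot(self.model.geometry)

    @property
    def plateau(self) -> float:
        """Predicted long-time cumulative release percent."""
        return plateau_percent(self.params, self.model._c_initial_si)

    def predict(self, times_h=None) -> np.ndarray:
        """Modelled cumulative release percent at ``times_h`` (defaults
        to the observation times)."""
        t = self.model.curve.times if times_h is None else np.asarray(times_h, float)
        return self.model.simulate(self.params, t).cumulative_percent

    def summary(self) -> str:
        fr = self.fit_result
        lines = [
            "Fickian release model (axial diffusion, Robin surface)",
            "=" * 58,
            f"observations:        {len(self.model.curve)}",
            f"free parameters:     {', '.join(fr.free)}",
            f"D_eff  [m^2/s]:      {self.d_eff:.4e}",
            f"k      [m/s]:        {self.k:.4e}",
            f"C_eq   [ug/mL]:      {self.c_eq_ug_ml:.4e}",
            f"Biot number kL/D:    {self.biot:.3g}",
            f"plateau [% release]: {self.plateau:.2f}",
            f"SSE [percent^2]:     {fr.sse:.4e}",
            f"R^2:                 {fr.r_squared:.4f}",
            f"objective evals:     {fr.n_evaluations}",
            f"GA converged early:  {fr.converged}",
            f"seed:                {fr.seed}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed points and fitted curve on one axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        obs = self.model.curve
        ax.plot(obs.times, obs.cumulative_percent, "o", label="observed")
        t_dense = np.linspace(max(obs.times[0], 1e-3), obs.times[-1], 200)
        ax.plot(t_dense, self.predict(t_dense), "-", label="model")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("cumulative release (%)")
        ax.legend()
        return ax


class KorsmeyerPeppas:
    """Early-window power-law model ``M_t/M_inf = a t^n``.

    Accepts one curve or a sequence of replicate curves; with
    replicates the fit is performed per replicate and the exponent is
    reported as mean +/- SD across them.
    """

    def __init__(self, curves, window_h: float = DEFAULT_WINDOW_H):
        if isinstance(curves, ReleaseCurve):
            curves = [curves]
        self.curves = list(curves)
        if not self.curves:
            raise InvalidParameterError("need at least one curve")
        self.window_h = float(window_h)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, m_infinity: float = 1.0, **kwargs):
        """Build from long-format data with ``time_h``, ``cumulative_percent``
        and an optional ``replicate_id`` column."""
        if "replicate_id" in data.columns:
            groups = [g for _, g in data.groupby("replicate_id", sort=True)]
        else:
            groups = [data]
        curves = [
            ReleaseCurve(
                times=g["time_h"].to_numpy(float),
                cumulative_mass=g["cumulative_percent"].to_numpy(float) / 100.0 * m_infinity,
                m_infinity=m_infinity,
            )
            for g in groups
        ]
        return cls(curves, **kwargs)

    def fit(self) -> "KorsmeyerPeppasResults":
        fits = [fit_korsmeyer_peppas(c, self.window_h) for c in self.curves]
        return KorsmeyerPeppasResults(self, fits)


@dataclass
class KorsmeyerPeppasResults:
    model: KorsmeyerPeppas
    replicate_fits: list

    @property
    def n(self) -> float:
        """Release exponent (mean across replicates)."""
        return float(np.mean([f.n for f in self.replicate_fits]))

    @property
    def n_sd(self) -> float:
        vals = [f.n for f in self.replicate_fits]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    @property
    def a(self) -> float:
        return float(np.mean([f.a for f in self.replicate_fits]))

    @property
    def rsquared(self) -> float:
        return float(np.mean([f.r_squared for f in self.replicate_fits]))

    @property
    def mechanism(self) -> str:
        from .kinetics import classify_mechanism

        return classify_mechanism(self.n)

    def summary(self) -> str:
        lines = [
            "Korsmeyer-Peppas power-law fit",
            "=" * 40,
            f"replicates:      {len(self.replicate_fits)}",
            f"window:          0-{self.model.window_h:g} h",
            f"n (exponent):    {self.n:.4f} +/- {self.n_sd:.4f}",
            f"a [frac/h^n]:    {self.a:.4f}",
            f"R^2 (log-log):   {self.rsquared:.4f}",
            f"mechanism:       {self.mechanism}",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "replicate": i,
                    "a": f.a,
                    "n": f.n,
                    "r_squared": f.r_squared,
                    "mechanism": f.mechanism,
                    "n_points": f.n_points,
                }
                for i, f in enumerate(self.replicate_fits)
            ]
        )
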