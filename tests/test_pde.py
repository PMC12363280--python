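"""Forward-solver tests: steady states, oracle agreement, convergence
order, mass balance, maximum principle and input validation."""

import numpy as np
import pytest

from gelrelease import (
    ConcentrationProfile,
    Discretization,
    HydrogelGeometry,
    TransportParameters,
    analytic_release_fraction,
    crank_nicolson_step,
    cumulative_mass,
    loaded_mass,
    plateau_percent,
    solve_release,
)
from gelrelease.exceptions import (
    AccuracyWarning,
    InvalidParameterError,
    MassBalanceError,
)

OBS_H = np.array([0.5, 1, 2, 4, 6, 8, 24, 48, 72, 120, 144, 168], dtype=float)
C0 = 4.0e5  # 0.4 µg/mL in µg/m^3


class TestSteadyStates:
    def test_equilibrium_initial_state_releases_nothing(self, geometry, default_disc):
        """Starting at the pseudo-equilibrium concentration, no net release."""
        p = TransportParameters(d_eff=1e-9, k=1e-5, c_eq=C0)
        curve, _ = solve_release(geometry, p, C0, default_disc, OBS_H)
        assert np.all(np.abs(curve.cumulative_percent) < 1e-9)

    def test_sealed_gel_releases_nothing(self, geometry, default_disc):
        """k = 0 seals both faces: zero release at all times."""
        p = TransportParameters(d_eff=1e-9, k=0.0, c_eq=0.0)
        curve, _ = solve_release(geometry, p, C0, default_disc, OBS_H)
        assert np.all(np.abs(curve.cumulative_percent) < 1e-9)

    def test_uniform_profiles_are_fixed_points_of_cn_step(self, geometry, default_disc):
        z = np.linspace(0, geometry.height, default_disc.n_nodes)
        # sealed gel, any uniform level
        prof = ConcentrationProfile(z=z, c=np.full(z.size, C0), t=0.0)
        p = TransportParameters(d_eff=1e-9, k=0.0, c_eq=0.0)
        out = crank_nicolson_step(prof, p, geometry, default_disc)
        np.testing.assert_allclose(out.c, prof.c, rtol=1e-13)
        # open gel already at equilibrium
        p = TransportParameters(d_eff=1e-9, k=1e-5, c_eq=C0)
        out = crank_nicolson_step(prof, p, geometry, default_disc)
        np.testing.assert_allclose(out.c, prof.c, rtol=1e-13)


class TestOracleAgreement:
    def test_release_at_six_hours_matches_series_oracle(
        self, geometry, default_disc, alginate_params
    ):
        """Default-grid solution vs the eigenfunction series at 6 h."""
        curve, _ = solve_release(geometry, alginate_params, C0, default_disc, OBS_H)
        got = curve.cumulative_fraction[OBS_H == 6.0][0]
        want = analytic_release_fraction(alginate_params, geometry, C0, 6.0)
        assert abs(got - want) < 1e-2  # documented bound at the default grid

    @pytest.mark.parametrize("biot", [0.1, 1.0, 10.0, 100.0])
    def test_oracle_equivalence_across_biot(self, geometry, biot):
        """Max release-fraction error < 1% of M_inf on the default grid and
        < 0.1% at tenfold refinement, across four decades of Biot number."""
        d_eff = 1.04e-9
        p = TransportParameters(d_eff=d_eff, k=biot * d_eff / geometry.height, c_eq=0.0)
        for disc, bound in [
            (Discretization(31, 300.0), 1e-2),
            (Discretization(301, 30.0), 1e-3),
        ]:
            curve, _ = solve_release(geometry, p, C0, disc, OBS_H)
            oracle = np.array(
                [analytic_release_fraction(p, geometry, C0, t) for t in OBS_H]
            )
            assert np.max(np.abs(curve.cumulative_fraction - oracle)) < bound

    def test_series_limits(self, geometry, alginate_params):
        assert analytic_release_fraction(alginate_params, geometry, C0, 0.0) == 0.0
        assert analytic_release_fraction(alginate_params, geometry, C0, 1e4) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_series_is_monotone_in_time(self, geometry, alginate_params):
        times = np.linspace(0.1, 48, 40)
        vals = [analytic_release_fraction(alginate_params, geometry, C0, t) for t in times]
        assert np.all(np.diff(vals) > 0)

    def test_large_biot_limit_matches_perfect_sink_series(self, geometry):
        """As k -> infinity the series collapses to the textbook
        perfect-sink slab solution (eigenvalues (2m-1) pi / 2)."""
        d_eff = 1.0e-9
        p = TransportParameters(d_eff=d_eff, k=1.0, c_eq=0.0)  # Biot = 5e6
        for t_h in (1.0, 6.0, 24.0):
            fo = d_eff * t_h * 3600.0 / geometry.height**2
            m = np.arange(1, 200)
            lam = (2 * m - 1) * np.pi / 2
            sink = 1.0 - np.sum(2.0 / lam**2 * np.exp(-(lam**2) * fo))
            got = analytic_release_fraction(p, geometry, C0, t_h)
            assert got == pytest.approx(sink, abs=1e-6)


class TestConvergence:
    def test_single_step_error_is_second_order(self, geometry, alginate_params):
        """Halving the step size of the plain CN step shrinks the error
        about fourfold (Richardson comparison from a smooth state)."""
        disc = Discretization(31, 300.0)
        # smooth state: run the full solver to 2 h first
        _, profs = solve_release(geometry, alginate_params, C0, disc, [2.0])
        start = profs[0]

        def advance(dt, n_steps):
            d = Discretization(disc.n_nodes, dt)
            prof = start
            for _ in range(n_steps):
                prof = crank_nicolson_step(prof, alginate_params, geometry, d)
            return prof.c

        c1 = advance(300.0, 1)
        c2 = advance(150.0, 2)
        c4 = advance(75.0, 4)
        ratio = np.linalg.norm(c1 - c2) / np.linalg.norm(c2 - c4)
        assert 3.0 < ratio < 5.0

    def test_full_solution_richardson_ratios(self, geometry, alginate_params):
        """Spatial and temporal refinement both show ~4x error contraction."""

        def frac_at_6h(n_nodes, dt):
            curve, _ = solve_release(
                geometry, alginate_params, C0, Discretization(n_nodes, dt), [6.0]
            )
            return curve.cumulative_fraction[0]

        f_t = [frac_at_6h(31, dt) for dt in (300.0, 150.0, 75.0)]
        ratio_t = (f_t[0] - f_t[1]) / (f_t[1] - f_t[2])
        assert 3.5 < ratio_t < 4.5

        f_z = [frac_at_6h(n, 10.0) for n in (16, 31, 61)]
        ratio_z = (f_z[0] - f_z[1]) / (f_z[1] - f_z[2])
        assert 3.5 < ratio_z < 4.5


class TestMassBalance:
    def test_trapezoid_release_trivial_and_linear(self, geometry):
        n = 30
        z = np.linspace(0, geometry.height, n)
        m_inf = loaded_mass(geometry, C0)
        uniform = ConcentrationProfile(z=z, c=np.full(n, C0), t=0.0)
        assert cumulative_mass(uniform, geometry, m_inf) == pytest.approx(0.0, abs=1e-12 * m_inf)
        empty = ConcentrationProfile(z=z, c=np.zeros(n), t=0.0)
        assert cumulative_mass(empty, geometry, m_inf) == pytest.approx(m_inf)
        # linear profile: trapezoid is exact, integral = c0 L / 2
        linear = ConcentrationProfile(z=z, c=C0 * z / geometry.height, t=0.0)
        expect = m_inf - geometry.cross_section * C0 * geometry.height / 2.0
        assert cumulative_mass(linear, geometry, m_inf) == pytest.approx(expect, rel=1e-14)

    def test_profile_integral_agrees_with_boundary_flux_integral(
        self, geometry, alginate_params
    ):
        """Released mass from the profile integral vs the time-integrated
        Robin boundary flux: 0.5% of M_inf on the default grid, 0.05% at
        tenfold refinement."""
        m_inf = loaded_mass(geometry, C0)
        for disc, bound in [
            (Discretization(31, 300.0), 5e-3),
            (Discretization(301, 30.0), 5e-4),
        ]:
            curve, _ = solve_release(
                geometry, alginate_params, C0, disc, OBS_H, track_flux=True
            )
            d = curve.diagnostics
            gap = np.max(
                np.abs(d["released_flux_integral"] - d["released_profile_integral"])
            )
            assert gap < bound * m_inf


class TestQualitativeBehaviour:
    def test_discrete_maximum_principle(self, geometry, default_disc):
        """Concentration stays within [c_eq, c_initial] and the release
        curve is non-decreasing when c_eq <= c_initial."""
        p = TransportParameters(d_eff=1.04e-9, k=4.13e-5, c_eq=0.35 * C0)
        curve, profs = solve_release(geometry, p, C0, default_disc, OBS_H)
        assert np.all(np.diff(curve.cumulative_percent) >= -1e-10)
        for prof in profs:
            assert prof.c.min() >= p.c_eq - 1e-9 * C0
            assert prof.c.max() <= C0 + 1e-9 * C0

    def test_uptake_when_gel_starts_below_equilibrium(self, geometry, default_disc):
        """c_initial < c_eq reverses the gradient: the gel takes mass up
        (negative 'release'), approaching the equilibrium level."""
        p = TransportParameters(d_eff=1.04e-9, k=4.13e-5, c_eq=C0)
        curve, profs = solve_release(geometry, p, 0.5 * C0, default_disc, OBS_H)
        assert curve.cumulative_mass[-1] < 0
        assert profs[-1].c.max() <= C0 * (1 + 1e-9)

    def test_long_time_release_hits_plateau(self, geometry, default_disc):
        """Past dimensionless time D t / L^2 = 3 the cumulative percent is
        within 0.1 points of the analytic plateau 100 (1 - c_eq/c0)."""
        p = TransportParameters(d_eff=1.04e-9, k=4.13e-5, c_eq=0.5393 * C0)
        t_large_h = 3.2 * geometry.height**2 / p.d_eff / 3600.0
        curve, _ = solve_release(geometry, p, C0, default_disc, [t_large_h])
        assert abs(curve.cumulative_percent[-1] - plateau_percent(p, C0)) < 0.1

    def test_plateau_percent_limits(self):
        p_sink = TransportParameters(d_eff=1e-9, k=1e-5, c_eq=0.0)
        assert plateau_percent(p_sink, C0) == 100.0
        p_eq = TransportParameters(d_eff=1e-9, k=1e-5, c_eq=C0)
        assert plateau_percent(p_eq, C0) == 0.0
        with pytest.raises(InvalidParameterError):
            plateau_percent(p_sink, 0.0)


class TestValidation:
    def test_invalid_geometry_and_parameters_raise(self):
        with pytest.raises(InvalidParameterError):
            HydrogelGeometry(radius=-1e-3, height=5e-3)
        with pytest.raises(InvalidParameterError):
            HydrogelGeometry(radius=3e-3, height=0.0)
        with pytest.raises(InvalidParameterError):
            TransportParameters(d_eff=0.0, k=1e-5)
        with pytest.raises(InvalidParameterError):
            TransportParameters(d_eff=1e-9, k=-1e-5)
        with pytest.raises(InvalidParameterError):
            Discretization(n_nodes=2)

    def test_unsorted_observation_times_raise(self, geometry, default_disc, alginate_params):
        with pytest.raises(InvalidParameterError):
            solve_release(geometry, alginate_params, C0, default_disc, [4.0, 2.0])

    def test_oversized_time_step_warns_but_runs(self, geometry, alginate_params):
        """A dt above the documented accuracy bound warns; Crank-Nicolson
        itself is unconditionally stable so the solve still completes."""
        coarse = Discretization(n_nodes=31, dt=900.0)
        with pytest.warns(AccuracyWarning):
            curve, _ = solve_release(geometry, alginate_params, C0, coarse, [24.0, 168.0])
        assert 0.0 < curve.cumulative_percent[-1] <= 100.0 + 1e-6

    def test_negative_released_mass_raises_mass_balance_error(self, geometry):
        z = np.linspace(0, geometry.height, 31)
        overfull = ConcentrationProfile(z=z, c=np.full(31, 2 * C0), t=0.0)
        with pytest.raises(MassBalanceError):
            cumulative_mass(overfull, geometry, loaded_mass(geometry, C0))

    def test_profiles_are_returned_on_the_grid(self, geometry, default_disc, alginate_params):
        curve, profs = solve_release(
            geometry, alginate_params, C0, default_disc, [0.0, 1.0, 6.0]
        )
        assert len(profs) == 3
        for prof in profs:
            assert prof.z[0] == 0.0
            assert prof.z[-1] == pytest.approx(geometry.height)
            assert prof.z.size == default_disc.n_nodes
        np.testing.assert_allclose(profs[0].c, C0)  # t = 0 is the initial state
        assert curve.cumulative_mass[0] == 0.0
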