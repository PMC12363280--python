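"""GA parameter estimation: objective definition, determinism,
monotone improvement, identifiability diagnostics, recovery."""

import dataclasses

import numpy as np
import pytest

from gelrelease import (
    Discretization,
    GAConfig,
    ReleaseCurve,
    TransportParameters,
    cumulative_from_supernatants,
    estimate,
    objective,
    profile_objective,
    solve_release,
)
from gelrelease.exceptions import IdentifiabilityWarning, InvalidParameterError
from gelrelease.synthetic import REFERENCE_CONDITIONS, NoiseModel, generate_static

C0 = 4.0e5  # 0.4 µg/mL in µg/m^3
OBS_H = np.array([0.5, 1, 2, 4, 6, 8, 24, 48, 72, 120, 144, 168], dtype=float)

SMALL_GA = dict(population_size=16, generations=12, stagnation_patience=6)


@pytest.fixture(scope="module")
def truth_curve(request):
    """Noise-free curve generated with the alginate 0.4 µg/mL parameters."""
    truth = REFERENCE_CONDITIONS["alginate-0.4"]
    ds = generate_static(truth, noise=NoiseModel(0.0), n_replicates=1, seed=11)
    return truth, cumulative_from_supernatants(ds.replicates[0])


class TestObjective:
    def test_zero_at_generating_parameters(self, geometry, default_disc, truth_curve):
        truth, curve = truth_curve
        assert objective(truth.params, curve, truth.geometry, default_disc,
                         truth.c_initial_si) < 1e-18

    def test_uniform_shift_by_one_point_costs_m(self, geometry, default_disc, truth_curve):
        truth, curve = truth_curve
        shifted = dataclasses.replace(
            curve, cumulative_mass=curve.cumulative_mass + 0.01 * curve.m_infinity
        )
        val = objective(truth.params, shifted, truth.geometry, default_disc,
                        truth.c_initial_si)
        assert val == pytest.approx(len(curve), rel=1e-6)

    def test_locally_identifiable_in_d_eff(self, default_disc, truth_curve):
        """Perturbing D_eff by +-10% off a noise-free curve strictly
        increases the misfit on both sides."""
        truth, curve = truth_curve
        for factor in (0.9, 1.1):
            p = dataclasses.replace(truth.params, d_eff=truth.d_eff * factor)
            assert objective(p, curve, truth.geometry, default_disc,
                             truth.c_initial_si) > 1.0


class TestGA:
    def test_seed_determinism(self, default_disc, truth_curve):
        truth, curve = truth_curve
        kwargs = dict(
            free_params=("d_eff", "k"),
            fixed={"c_eq": truth.params.c_eq},
            config=GAConfig(seed=5, polish=False, **SMALL_GA),
        )
        r1 = estimate(curve, truth.geometry, default_disc, truth.c_initial_si, **kwargs)
        r2 = estimate(curve, truth.geometry, default_disc, truth.c_initial_si, **kwargs)
        assert r1.params == r2.params
        assert r1.sse == r2.sse
        assert r1.n_evaluations == r2.n_evaluations

    def test_best_objective_is_monotone_per_generation(self, default_disc, truth_curve):
        truth, curve = truth_curve
        res = estimate(
            curve, truth.geometry, default_disc, truth.c_initial_si,
            free_params=("d_eff", "k"), fixed={"c_eq": truth.params.c_eq},
            config=GAConfig(seed=2, polish=False, **SMALL_GA),
        )
        assert np.all(np.diff(res.best_per_generation) <= 0.0)

    def test_collapsed_bounds_return_that_point(self, default_disc, truth_curve):
        truth, curve = truth_curve
        point = {
            "d_eff": (np.log10(2e-9), np.log10(2e-9)),
            "k": (np.log10(1e-5), np.log10(1e-5)),
        }
        res = estimate(
            curve, truth.geometry, default_disc, truth.c_initial_si,
            free_params=("d_eff", "k"), fixed={"c_eq": truth.params.c_eq},
            config=GAConfig(seed=0, bounds=point, polish=False, **SMALL_GA),
        )
        assert res.params.d_eff == pytest.approx(2e-9, rel=1e-12)
        assert res.params.k == pytest.approx(1e-5, rel=1e-12)

    def test_small_ga_with_polish_recovers_noise_free_truth(self, default_disc, truth_curve):
        """Even a small population finds the basin; the simplex polish
        then drives the noise-free misfit to numerical zero."""
        truth, curve = truth_curve
        res = estimate(
            curve, truth.geometry, default_disc, truth.c_initial_si,
            free_params=("d_eff", "k"), fixed={"c_eq": truth.params.c_eq},
            config=GAConfig(seed=3, **SMALL_GA),
        )
        assert res.params.d_eff == pytest.approx(truth.d_eff, rel=5e-3)
        assert res.r_squared > 0.9999

    def test_median_d_eff_robust_to_measurement_noise(self, default_disc):
        """Replicate fits on 5%-noise data: the median recovered D_eff
        stays within 10% of the truth (scaled-down replication)."""
        truth = REFERENCE_CONDITIONS["alginate-0.4"]
        ds = generate_static(truth, noise=NoiseModel(0.05), n_replicates=5, seed=21)
        estimates = []
        for i, rep in enumerate(ds.replicates):
            curve = cumulative_from_supernatants(rep)
            res = estimate(
                curve, truth.geometry, default_disc, truth.c_initial_si,
                free_params=("d_eff", "k"), fixed={"c_eq": truth.params.c_eq},
                config=GAConfig(seed=100 + i, **SMALL_GA),
            )
            estimates.append(res.params.d_eff)
        assert np.median(estimates) == pytest.approx(truth.d_eff, rel=0.10)

    def test_invalid_requests_raise(self, default_disc, truth_curve):
        truth, curve = truth_curve
        with pytest.raises(InvalidParameterError):
            estimate(curve, truth.geometry, default_disc, truth.c_initial_si,
                     free_params=("d_eff", "bogus"))
        with pytest.raises(InvalidParameterError):
            estimate(curve, truth.geometry, default_disc, truth.c_initial_si,
                     free_params=("d_eff",))  # k neither free nor fixed
        short = ReleaseCurve(times=np.array([1.0, 2.0, 3.0]),
                             cumulative_mass=np.array([1.0, 2.0, 3.0]), m_infinity=10.0)
        with pytest.raises(InvalidParameterError):
            estimate(short, truth.geometry, default_disc, truth.c_initial_si)
        with pytest.raises(InvalidParameterError):
            GAConfig(population_size=4)
        with pytest.raises(InvalidParameterError):
            GAConfig(crossover_rate=1.5)


class TestIdentifiability:
    def test_k_direction_is_flat_at_high_biot(self, default_disc, truth_curve):
        """At Biot ~200 the release curve barely feels k: the k-profile
        of the objective is flat and a warning is emitted."""
        truth, curve = truth_curve
        grid = truth.k * np.array([0.5, 0.8, 1.0, 1.25, 2.0])
        with pytest.warns(IdentifiabilityWarning):
            values = profile_objective(
                curve, truth.geometry, default_disc, truth.c_initial_si,
                "k", grid, at=truth.params,
            )
        assert values.min() >= 0.0

    def test_d_eff_direction_is_sharply_curved(self, default_disc, truth_curve):
        truth, curve = truth_curve
        grid = truth.d_eff * np.array([0.5, 0.8, 1.0, 1.25, 2.0])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error", IdentifiabilityWarning)
            values = profile_objective(
                curve, truth.geometry, default_disc, truth.c_initial_si,
                "d_eff", grid, at=truth.params,
            )
        assert np.argmin(values) == 2  # minimum at the truth
        assert values.max() > 100.0 * max(values[2], 1e-30)
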