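import numpy as np
import pytest

from gelrelease import (
    Discretization,
    HydrogelGeometry,
    ReleaseCurve,
    TransportParameters,
)

#: standard cylinder: 6.5 mm diameter, 5 mm height
@pytest.fixture
def geometry():
    return HydrogelGeometry(radius=3.25e-3, height=5.0e-3)


@pytest.fixture
def default_disc():
    return Discretization(n_nodes=31, dt=300.0)


@pytest.fixture
def alginate_params():
    """Fitted transport parameters of the 1% alginate gel at the lowest
    loading, perfect-sink variant (c_eq = 0)."""
    return TransportParameters(d_eff=1.04e-9, k=4.13e-5, c_eq=0.0)


def make_power_curve(a, n, times):
    """Noise-free power-law release curve M_t/M_inf = a t^n (fractions)."""
    t = np.asarray(times, dtype=float)
    return ReleaseCurve(times=t, cumulative_mass=a * t**n, m_infinity=1.0)
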