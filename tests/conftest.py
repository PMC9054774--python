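import numpy as np
import pytest

from windhover.flow import VelocityTimeSeries
from windhover.synthetic import (
    FlightVolume,
    GridSpec,
    RampGeometry,
    TurbulenceSpec,
    generate_turbulence,
    generate_updraft_field,
)

# published turbulence-grid targets: (intensity fraction, length scale m)
GRID_A = (0.073, 0.22)
GRID_B = (0.126, 0.31)


@pytest.fixture(scope="session")
def ramp():
    return RampGeometry()


@pytest.fixture(scope="session")
def flight_volume():
    return FlightVolume()


@pytest.fixture(scope="session")
def grid_b_spec():
    return TurbulenceSpec(
        mean_speed=6.0, intensity=GRID_B[0], length_scale=GRID_B[1],
        sample_rate=1250.0, duration=60.0, seed=1,
    )


@pytest.fixture(scope="session")
def grid_b_series(grid_b_spec):
    return generate_turbulence(grid_b_spec)


@pytest.fixture(scope="session")
def default_map(ramp, flight_volume):
    return generate_updraft_field(
        ramp, 6.0, GridSpec.covering(flight_volume), flight_volume
    )


def make_series(u, v=None, w=None, sample_rate=1250.0):
    """Build a VelocityTimeSeries from component arrays (zeros by default)."""
    u = np.asarray(u, dtype=float)
    n = len(u)
    zeros = np.zeros(n)
    return VelocityTimeSeries(
        t=np.arange(n) / sample_rate,
        u=u,
        v=zeros if v is None else np.asarray(v, dtype=float),
        w=zeros if w is None else np.asarray(w, dtype=float),
        sample_rate=sample_rate,
    )
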