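import numpy as np
import pytest

from fsflim import (
    Fluorophore,
    PhantomScene,
    SensorConfig,
    SimulationParams,
    SpectralAxis,
    TimeAxis,
    default_pde_curve,
    simulate_cube,
)


@pytest.fixture(scope="session")
def default_axis() -> SpectralAxis:
    """The instrument's spectral axis: 512 channels over 500-760 nm."""
    return SpectralAxis()


@pytest.fixture(scope="session")
def raw_time_axis() -> TimeAxis:
    """32 raw bins of 1.5625 ns spanning the 50 ns laser period."""
    return TimeAxis()


@pytest.fixture(scope="session")
def small_axis() -> SpectralAxis:
    """Reduced 64-channel axis over the same range, for fast cube tests."""
    return SpectralAxis(n_channels=64)


@pytest.fixture(scope="session")
def sensor(small_axis) -> SensorConfig:
    return SensorConfig(
        dark_count_rate=100.0,
        pde_curve=default_pde_curve(small_axis),
        pde_peak=0.17,
        irf_fwhm=100.0,
    )


@pytest.fixture(scope="session")
def two_fluor_phantom(small_axis):
    """Two spectrally disjoint fluorophores on image halves, known lifetimes.

    Left half: short-lived emitter at 560 nm (tau 1.5 ns); right half:
    long-lived emitter at 690 nm (tau 3.5 ns).  Brightness gives >2000
    detected photons in the bright channels at 500 µs dwell.
    """
    short = Fluorophore("short", 560.0, 25.0, 1.5, 40.0)
    long = Fluorophore("long", 690.0, 25.0, 3.5, 40.0)
    w_short = np.zeros((32, 32))
    w_short[:, :16] = 1.0
    w_long = np.zeros((32, 32))
    w_long[:, 16:] = 1.0
    return PhantomScene(32, 32, [short, long], [w_short, w_long])


@pytest.fixture(scope="session")
def chained_cube(two_fluor_phantom, sensor, small_axis, raw_time_axis):
    """Simulated chained-readout cube of the two-fluorophore phantom."""
    params = SimulationParams(dwell_time=500.0, seed=11, chained=True)
    return simulate_cube(two_fluor_phantom, sensor, small_axis, raw_time_axis, params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


def random_cube(rng, rows=4, cols=4, channels=8, bins=8, chained=False):
    """Small random valid FlimCube for round-trip / conservation tests."""
    from fsflim import FlimCube

    cap = (2**20 - 1) if chained else (2**10 - 1)
    counts = rng.integers(0, min(cap, 500), size=(rows, cols, channels, bins))
    return FlimCube(
        counts=counts.astype(np.uint32),
        spectral_axis=SpectralAxis(n_channels=channels),
        time_axis=TimeAxis(n_bins=bins, bin_width=50.0 / bins),
        chained=chained,
        dwell_time=500.0,
        provenance={"origin": "test"},
    )
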