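import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from ecisbarrier.model import (  # noqa: E402
    ComplexSpectrum,
    ElectrodeModel,
    FrequencyGrid,
    naked_impedance,
    well_impedance,
)


@pytest.fixture(scope="session")
def electrode() -> ElectrodeModel:
    return ElectrodeModel()


@pytest.fixture(scope="session")
def grid() -> FrequencyGrid:
    return FrequencyGrid.default()


@pytest.fixture(scope="session")
def reference_spectrum(electrode, grid) -> ComplexSpectrum:
    f = grid.as_array()
    z = naked_impedance(electrode, f) / electrode.electrode_area + electrode.series_resistance
    return ComplexSpectrum(grid, z)


def synth_spectrum(electrode, grid, params, noise_sd=0.0, rng=None) -> ComplexSpectrum:
    """Forward-model spectrum of a confluent well, optionally noisy."""
    f = grid.as_array()
    z = well_impedance(electrode, params, f)
    if noise_sd:
        z = (z.real * (1 + noise_sd * rng.standard_normal(f.size))
             + 1j * z.imag * (1 + noise_sd * rng.standard_normal(f.size)))
    return ComplexSpectrum(grid, z)
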