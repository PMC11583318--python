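import numpy as np
import pytest

from nanotrace import AcquisitionSettings, NoiseModel, ParticlePopulation


@pytest.fixture
def settings():
    """Default acquisition: 100 us dwell, 45 s, 0.5 mL/min uptake."""
    return AcquisitionSettings()


@pytest.fixture
def short_settings():
    """5 s acquisition for cheap simulations."""
    return AcquisitionSettings(acquisition_time=5.0)


@pytest.fixture
def noise():
    return NoiseModel(baseline_mean=1.0)


@pytest.fixture
def gold():
    """60 nm monodisperse gold population factory."""

    def make(number_concentration=0.0, geometric_sd=1.0, median_diameter=60.0):
        return ParticlePopulation(
            element="Au",
            density=19.32,
            element_mass_fraction=1.0,
            median_diameter=median_diameter,
            geometric_sd=geometric_sd,
            number_concentration=number_concentration,
        )

    return make


def toy_trace(counts, dwell_time=1.0, flow_rate=0.5):
    """A TimeTrace with one dwell per list entry (1 s dwells)."""
    from nanotrace import TimeTrace

    counts = np.asarray(counts)
    s = AcquisitionSettings(
        dwell_time=dwell_time,
        acquisition_time=dwell_time * len(counts),
        flow_rate=flow_rate,
    )
    return TimeTrace(counts=counts, settings=s)
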