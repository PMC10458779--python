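import numpy as np
import pytest

from tuberflux import ChamberSpec, Injection, PlantParams, ScenarioConfig, simulate

DAY = 86400.0


@pytest.fixture(scope="session")
def chamber40():
    return ChamberSpec(volume=40.0)


@pytest.fixture(scope="session")
def plant_default():
    return PlantParams()


@pytest.fixture(scope="session")
def sealed_experiment():
    """The reference sealed scenario: 20 days, 60 s step, no leak, no noise."""
    cfg = ScenarioConfig(noise_sd_ppm=0.0)
    return simulate(cfg)


@pytest.fixture(scope="session")
def unsealed_experiment():
    """Leaky chamber (k = 2e-6 1/s) with two mid-run CO2 injections, no noise."""
    chamber = ChamberSpec(
        volume=40.0,
        leak_coefficient=2e-6,
        ambient_co2_ppm=420.0,
        injections=(
            Injection(time=6 * DAY, amount=2.0e23),
            Injection(time=12 * DAY, amount=2.0e23),
        ),
    )
    cfg = ScenarioConfig(chamber=chamber, noise_sd_ppm=0.0)
    return simulate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20230816)
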