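import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from renschrule import SimulationConfig, SpeciesRecord, TraitTable

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_table() -> TraitTable:
    """Five species, four female-biased and one male-biased."""
    rows = [
        ("Rana_a", 60.0, 50.0, 5.0, 4.0),
        ("Rana_b", 55.0, 52.0, 4.5, 4.0),
        ("Bufo_a", 80.0, 70.0, 6.0, 5.0),
        ("Bufo_b", 45.0, 40.0, 4.0, 3.5),
        ("Hyla_a", 38.0, 42.0, 3.0, 3.5),
    ]
    return TraitTable(
        records=[
            SpeciesRecord(
                species=s, female_size=fs, male_size=ms, female_age=fa, male_age=ma
            )
            for s, fs, ms, fa, ma in rows
        ],
        provenance="toy",
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20130309)


@pytest.fixture
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=11)
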