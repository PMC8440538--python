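import pytest

from ebimet import chem
from ebimet.simulate import SimulationConfig


@pytest.fixture
def caffeine():
    return chem.parse_formula("C8H10N4O2")


@pytest.fixture
def bupropion():
    return chem.parse_formula("C13H18ClNO")


@pytest.fixture
def zero_noise_cfg():
    """Noise-free simulation: deterministic ground-truth recovery."""
    return SimulationConfig(
        seed=11,
        ppm_jitter_sd=0.0,
        rt_jitter_sd=0.0,
        intensity_noise_cv=0.0,
        missing_rate=0.0,
        n_background=40,
    )


@pytest.fixture
def default_rules():
    return chem.default_rules()
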