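import numpy as np
import pytest

from evlock.synth import SimulationConfig, UnitSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """A fast 1-kHz session with three filaments and three units."""
    return SimulationConfig(
        fs_raw=1000.0,
        n_trials_per_filament=2,
        filament_forces=(0.16, 0.4, 0.6),
        psychometric=(0.05, 8.0),  # almost every trial withdraws
        unit_specs=[
            UnitSpec(8.0, "excited", 40.0, 0.5, 1),
            UnitSpec(12.0, "inhibited", 0.5, 1.0, 2),
            UnitSpec(5.0, "none", waveform_class=2),
        ],
        seed=7,
    )
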