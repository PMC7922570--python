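import numpy as np
import pytest

from milkmir.grid import make_instrument_grid
from milkmir.spectra import SpectraSet
from milkmir.synthetic import TrialConfig, simulate_trial


@pytest.fixture(scope="session")
def instrument_grid():
    return make_instrument_grid(1060, 925, 5008)


@pytest.fixture(scope="session")
def effect_trial():
    """One synthetic trial with the standard TR3 effect (seed fixed)."""
    config = TrialConfig.default(seed=7)
    spectra, metadata, composition = simulate_trial(config)
    return spectra, metadata, composition


@pytest.fixture(scope="session")
def null_trial():
    """One synthetic trial with no treatment effect (seed fixed)."""
    config = TrialConfig.default(seed=11, effect_scale=0.0)
    return simulate_trial(config)


@pytest.fixture()
def small_spectra(instrument_grid):
    """Ten smooth random spectra on the instrument grid."""
    rng = np.random.default_rng(42)
    x = instrument_grid.points
    vals = np.vstack([
        0.5 + 0.1 * np.sin(x / (200 + 10 * i)) + rng.normal(0, 0.01, x.size)
        for i in range(10)
    ])
    return SpectraSet(sample_ids=[f"s{i}" for i in range(10)],
                      grid=instrument_grid, values=vals)
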