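import numpy as np
import pytest

from qenscell import (
    CellSpectrumModel,
    InstrumentPreset,
    ResolutionModel,
    generate,
    preset_in5,
    scenario,
)


@pytest.fixture(scope="session")
def in5():
    return preset_in5()


@pytest.fixture(scope="session")
def small_preset():
    """Reduced instrument layout for fast fit tests: 5 Q groups, 151 bins."""
    return InstrumentPreset(
        name="small",
        q_values=np.array([0.2, 0.4, 0.6, 0.8, 1.0]),
        energy_window_meV=(-1.5, 1.5),
        n_energy_bins=151,
        resolution=ResolutionModel.gaussian(0.010),
    )


@pytest.fixture(scope="session")
def medium_preset():
    """9 Q groups, 201 bins: enough Q leverage to identify tau_bulk."""
    return InstrumentPreset(
        name="medium",
        q_values=np.round(np.arange(0.2, 1.101, 0.1), 6),
        energy_window_meV=(-1.5, 1.5),
        n_energy_bins=201,
        resolution=ResolutionModel.gaussian(0.010),
    )


@pytest.fixture(scope="session")
def scenario_fits(in5):
    """Lazily computed noiseless global fits of the four measured conditions.

    Cached across the session so the recovery and sign-pattern checks
    share the same fits.
    """
    cache = {}

    def get(name):
        if name not in cache:
            truth = scenario(name)
            sset = generate(truth, in5, label=name)
            result = CellSpectrumModel(sset).fit(seed=1, n_starts=3)
            cache[name] = (truth, result)
        return cache[name]

    return get
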