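import numpy as np
import pytest

from synwm.neural_mass import (
    Architecture,
    MassState,
    PopulationParams,
    STPParams,
    StimulusSchedule,
)
from synwm.protocols import load_preset


@pytest.fixture(scope="session")
def stp():
    return STPParams()


@pytest.fixture(scope="session")
def single_pop_model():
    return load_preset("single_pop")


@pytest.fixture(scope="session")
def two_item_model():
    return load_preset("two_item")


@pytest.fixture(scope="session")
def multi_item_model():
    return load_preset("multi_item")


@pytest.fixture(scope="session")
def single_pop():
    """Single excitatory population at the two-pulse protocol parameters."""
    arch = Architecture.single_excitatory(15.0)
    pops = [PopulationParams(tau_m=15.0, H=0.0, Delta=0.25)]
    return arch, pops


@pytest.fixture(scope="session")
def multi_item_runs(multi_item_model):
    """Lazily computed multi-item loading runs keyed by the number of items.

    Shared across the band-power and memory-load tests so each run is
    integrated once per session.
    """
    from synwm.protocols import multi_item_run

    cache = {}

    def get(n_load):
        if n_load not in cache:
            cache[n_load] = multi_item_run(n_load, t_after=11500.0)
        return cache[n_load]

    return get
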