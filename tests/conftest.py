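import numpy as np
import pytest

from autoassoc import (
    GridSpec,
    NetworkConfig,
    NeuronParams,
    ThresholdTable,
    optimal_configs,
    run_sweep,
    select_optimal,
)


@pytest.fixture(scope="session")
def neuron_params():
    return NeuronParams()


@pytest.fixture(scope="session")
def table():
    """Shared spike-threshold table (covers the full parameter grid)."""
    return ThresholdTable.build()


@pytest.fixture(scope="session")
def desk_db(table):
    """Desk-scale sweep: 5 values/axis at 50% connectivity, loads 5 and 30."""
    spec = GridSpec().scaled(5, set_sizes=(5, 30))
    return run_sweep(spec, table, seed=1, connectivity_values=np.array([0.5]))


@pytest.fixture(scope="session")
def optimal_ensemble(desk_db):
    """Top-10 balanced networks at 50% connectivity, 30 stored patterns."""
    selected = select_optimal(desk_db, 0.5, 30, top_k=10)
    return optimal_configs(selected)


@pytest.fixture
def config():
    """A mid-grid wild-type-ish configuration."""
    return NetworkConfig(
        connectivity_level=0.5,
        g_max_ampa=5.0,
        gamma_ltd=2.0,
        relative_inhibition=5.0,
    )
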