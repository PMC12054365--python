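import numpy as np
import pandas as pd
import pytest

from sxcalib.reflections import UnmergedReflectionTable
from sxcalib.simulate import SimulationConfig, simulate_experiment


@pytest.fixture
def hand_table():
    """Tiny handcrafted table with exactly known group structure."""
    refl = pd.DataFrame(
        {
            "h": [1, 1, 1, 2, 2, 3],
            "k": [2, 2, 2, 0, 0, 1],
            "l": [3, 3, 3, 0, 0, 1],
            "lattice_id": ["a", "b", "c", "a", "b", "c"],
            "intensity": [1.0, 2.0, 3.0, 4.0, 6.0, 5.0],
            "sigma": [1.0, 1.0, 1.0, 1.0, 1.0, 2.0],
        }
    )
    lat = pd.DataFrame(
        {"lattice_id": ["a", "b", "c"], "cc": [0.9, 0.5, 0.2]}
    )
    return UnmergedReflectionTable(refl, lat)


@pytest.fixture(scope="session")
def small_sim():
    """Moderate model-conforming simulation shared across tests."""
    config = SimulationConfig(
        n_miller=400, mean_multiplicity=8.0, n_lattices=60, seed=7
    )
    table, truth = simulate_experiment(config)
    return config, table, truth


@pytest.fixture(scope="session")
def recovery_sim():
    """Full-scale (~1e5 obs) simulation at the documented study conditions."""
    config = SimulationConfig(seed=20260930)
    table, truth = simulate_experiment(config)
    return config, table, truth


@pytest.fixture(scope="session")
def mm24_halfnormal_fit(recovery_sim):
    """Half-normal MM24 fit of the full-scale simulation (shared: slow)."""
    from sxcalib.mm24 import fit_mm24

    _, table, _ = recovery_sim
    return fit_mm24(table, likelihood="half_normal")
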