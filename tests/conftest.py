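"""Shared fixtures: simulated sessions and their (scaled-down) fits.

Simulated datasets are generated at the package defaults (200 trials,
reference parameters, 1-up/1-down staircase over 0-3 mA).  Multi-start
fits use 16-20 Latin-hypercube starts instead of the production default
of 100 to keep the suite fast; the sorted-NLL step pattern shows roughly
a third of starts reaching the global plateau, so this is ample for
synthetic data.
"""

import numpy as np
import pytest

import nocifit as nf


@pytest.fixture(scope="session")
def reference_theta():
    return nf.reference_parameters()


@pytest.fixture(scope="session")
def constants():
    return nf.ModelConstants()


@pytest.fixture(scope="session")
def space():
    return nf.default_parameter_space()


@pytest.fixture(scope="session")
def ts1_dataset():
    return nf.simulate_dataset(nf.SimulationConfig(seed=11, design=nf.design_ts1()))


@pytest.fixture(scope="session")
def ts2_dataset():
    return nf.simulate_dataset(nf.SimulationConfig(seed=7, design=nf.design_ts2()))


@pytest.fixture(scope="session")
def small_dataset():
    """48-trial session for cheap optimisation tests."""
    return nf.simulate_dataset(
        nf.SimulationConfig(seed=5, design=nf.design_ts1(), n_total=48)
    )


@pytest.fixture(scope="session")
def ts1_fit(ts1_dataset):
    return nf.fit_hazard_model(ts1_dataset, n_starts=20, seed=0)


@pytest.fixture(scope="session")
def ts2_fit(ts2_dataset):
    return nf.fit_hazard_model(ts2_dataset, n_starts=16, seed=1)


@pytest.fixture(scope="session")
def random_params(space):
    """30 log-uniform parameter draws from the feasible space."""
    rng = np.random.default_rng(42)
    draws = []
    for _ in range(30):
        u = rng.uniform(size=6)
        draws.append(
            nf.HazardParams.from_array(
                10 ** (space.log_lower + u * (space.log_upper - space.log_lower))
            )
        )
    return draws
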