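import numpy as np
import pytest

from thermetab import micromet as mm
from thermetab.synthetic import generate_design, generate_met, generate_true_conductance


@pytest.fixture(scope="session")
def flight_met() -> mm.MetConditions:
    """The emulated midday flight conditions."""
    return generate_met()


@pytest.fixture(scope="session")
def flight_air(flight_met):
    return mm.air_properties(flight_met)


@pytest.fixture(scope="session")
def flight_res(flight_met):
    return mm.resistance_set(flight_met)


@pytest.fixture()
def rng():
    return np.random.default_rng(20120829)  # flight date as seed


@pytest.fixture()
def small_truth(flight_met):
    """18-plant ground truth at the default study conditions."""
    design = generate_design(6)
    return generate_true_conductance(design, seed=7, met=flight_met)


def random_met(rng) -> mm.MetConditions:
    """A physically plausible random weather snapshot (shared test helper)."""
    return mm.MetConditions(
        Ta=float(rng.uniform(10.0, 40.0)),
        RH=float(rng.uniform(20.0, 90.0)),
        u=float(rng.uniform(0.5, 5.0)),
        SWR=float(rng.uniform(100.0, 1000.0)),
        P=float(rng.uniform(9.0e4, 1.05e5)),
    )
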