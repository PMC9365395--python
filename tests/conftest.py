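import numpy as np
import pytest

import patchkin as pk

DEAD_TIME = 18.83e-6

S1_TRUTH = {
    "k_plus1_prime": 3900.0,
    "k_minus1_prime": 7600.0,
    "beta_1": 10000.0,
    "alpha_1": 310.0,
}


@pytest.fixture(scope="session")
def s1():
    return pk.scheme_preset("S1")


@pytest.fixture(scope="session")
def s1_generator(s1):
    return pk.build_generator(s1)


@pytest.fixture(scope="session")
def two_state():
    """Minimal C <-> O scheme, k_open = 100/s, k_close = 200/s."""
    return pk.KineticScheme(
        "two-state",
        (pk.State("C", "shut"), pk.State("O", "open")),
        (
            pk.Transition("C", "O", "k_open", 100.0),
            pk.Transition("O", "C", "k_close", 200.0),
        ),
    )


@pytest.fixture(scope="session")
def s1_recording(s1):
    """One conditioned recording simulated from the spontaneous scheme."""
    cfg = pk.SimulationConfig(scheme=s1, seed=101, n_events=10_000)
    return pk.impose_dead_time(pk.simulate_recording(cfg), DEAD_TIME)


def simulate_conditioned(scheme, seed, n_events, concentrations=None,
                         dead_time=DEAD_TIME):
    cfg = pk.SimulationConfig(
        scheme=scheme, seed=seed, n_events=n_events,
        concentrations=concentrations or {},
    )
    return pk.impose_dead_time(pk.simulate_recording(cfg), dead_time)
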