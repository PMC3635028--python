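"""Shared fixtures.  Network simulations are expensive, so the variant runs
used by the system-level tests are produced once per session at a reduced
scale (8 trials, 2.2 s per trial) and shared."""
import numpy as np
import pytest

from antlobe import engine, stimulus

WIRING_SEED = 7
ODOR_SEED = 11
MASTER_SEED = 3
N_TRIALS = 8
DURATION = 2200.0


@pytest.fixture(scope="session")
def odor():
    return stimulus.make_odor(ODOR_SEED)


@pytest.fixture(scope="session")
def odor_pair():
    """Two odors sharing all stimulated LNs and half the stimulated PNs."""
    return stimulus.make_odor_pair(0.5, 1.0, seed=ODOR_SEED)


def _run(variant, odor, n_trials=N_TRIALS, master=MASTER_SEED):
    cfg = engine.SimConfig(variant=variant, wiring_seed=WIRING_SEED,
                           master_seed=master, n_trials=n_trials,
                           duration=DURATION, odor=odor)
    return engine.run_experiment(cfg)


@pytest.fixture(scope="session")
def run_intact(odor):
    return _run("I", odor)


@pytest.fixture(scope="session")
def run_nogaba(odor):
    return _run("NG", odor)


@pytest.fixture(scope="session")
def run_noslow(odor):
    return _run("NS", odor)


@pytest.fixture(scope="session")
def pair_runs(odor_pair):
    """NS and I runs for both odors of the 50%-overlap pair (6 trials)."""
    o1, o2 = odor_pair
    return {
        ("NS", 1): _run("NS", o1, n_trials=6),
        ("NS", 2): _run("NS", o2, n_trials=6),
        ("I", 1): _run("I", o1, n_trials=6),
        ("I", 2): _run("I", o2, n_trials=6),
    }
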