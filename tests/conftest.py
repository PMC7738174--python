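import warnings
from types import SimpleNamespace

import numpy as np
import pytest

from burstcode import SimulationParams, generate_uniform_stimulus, simulate_ganglion_cell
from burstcode.pipeline import analyze

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_run():
    """Default-condition simulation (30 repeats x 120 s) analyzed end to end.

    Session-scoped: the parameter-recovery, reconstruction and information
    checks all read from this single run.
    """
    trace = generate_uniform_stimulus(120_000, 30.0, seed=DEFAULT_SEED)
    spikes, truth = simulate_ganglion_cell(
        trace, params=SimulationParams(n_rep=30), seed=DEFAULT_SEED + 100
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = analyze(spikes, trace, truth=truth)
    return SimpleNamespace(trace=trace, spikes=spikes, truth=truth, result=result)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
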