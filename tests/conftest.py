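import numpy as np
import pytest

from thymoatac import simulate as sim
from thymoatac.core import GenomicInterval, PeakSet


@pytest.fixture(scope="session")
def dataset():
    """One small synthetic dataset shared across tests (seed fixed)."""
    return sim.simulate_dataset(sim.SimulationParams(), seed=7)


@pytest.fixture(scope="session")
def sharp_pwm():
    return sim.builtin_pwms(gc=0.417)[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_peaks(triples, sample=""):
    return PeakSet([GenomicInterval(c, s, e) for c, s, e in triples], sample=sample)
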