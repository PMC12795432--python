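import numpy as np
import pytest

from octsim import (BeamGeometry, DetectionConfig, OpticalMedium,
                    SimulationConfig)


@pytest.fixture(scope="session")
def beam() -> BeamGeometry:
    """Standard 1300 nm SMF beam: w0 = 15 um, zR = 750 um, focus 2.57 mm."""
    return BeamGeometry(w0=15e-3, zR=750e-3, zf=2.57)


@pytest.fixture(scope="session")
def weak_medium() -> OpticalMedium:
    return OpticalMedium(mua=0.15, mus=0.25, g=0.3, n=1.33)


@pytest.fixture(scope="session")
def weak_config(beam, weak_medium) -> SimulationConfig:
    return SimulationConfig(beam=beam, medium=weak_medium,
                            detection=DetectionConfig(),
                            n_photons=100_000, seed=11)


@pytest.fixture(scope="session")
def weak_run(weak_config):
    """Moderate-size kernel run shared by record-level tests."""
    from octsim import run_simulation
    return run_simulation(weak_config.replace(n_photons=300_000))


class SequenceRNG:
    """Deterministic stand-in for a Generator: replays a fixed uniform
    sequence (used to drive single-photon histories by hand)."""

    def __init__(self, values):
        self._values = list(values)
        self._i = 0

    def random(self, size=None):
        if size is not None:
            out = np.array([self.random() for _ in range(int(size))])
            return out
        v = self._values[self._i]
        self._i += 1
        return v


@pytest.fixture
def sequence_rng():
    return SequenceRNG
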