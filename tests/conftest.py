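import numpy as np
import pytest

import laminargc as lg


@pytest.fixture(scope="session")
def coupled_session():
    """Pre-dimming session with a V1 gamma oscillator and a directed
    V1-granular -> V4-granular coupling (no evoked transient)."""
    cfg = lg.GeneratorConfig(
        n_trials_per_condition=30,
        n_channels=4,
        n_samples=512,
        oscillators=[lg.Oscillator(f0=40.0, bandwidth=12.0, probe="V1",
                                   amplitude=1.2)],
        couplings=[lg.Coupling("V1", [2], "V4", [2], lag=2, gain=0.4)],
        evoked=None,
        epoch_alignment="pre_dimming",
        seed=7,
    )
    return lg.generate_session(cfg)


@pytest.fixture(scope="session")
def evoked_session():
    """Full 16-contact two-probe session with the default granular sink."""
    cfg = lg.GeneratorConfig(
        n_trials_per_condition=10,
        oscillators=[lg.Oscillator(f0=40.0, bandwidth=12.0, probe="V1",
                                   amplitude=1.0)],
        seed=3,
    )
    return lg.generate_session(cfg)


@pytest.fixture(scope="session")
def taper():
    return lg.TaperSpec()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
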