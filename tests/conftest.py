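import numpy as np
import pytest

from phidyn.esn import (
    CPPProbeSpec,
    ESNConfig,
    ProtocolSpec,
    build_esn,
    make_cpp_probe,
    make_training_sequence,
    run_esn,
    train_readout,
)


@pytest.fixture(scope="session")
def small_cfg() -> ESNConfig:
    """A small reservoir for fast structural tests."""
    return ESNConfig(n_reservoir=40, seed=7)


@pytest.fixture(scope="session")
def small_protocol() -> ProtocolSpec:
    """A shortened training protocol with the same structure as the default."""
    return ProtocolSpec(pulse_len=60, gap=60, shift=20, k_total=3000,
                        invalid_start=1800)


@pytest.fixture(scope="session")
def small_probe() -> CPPProbeSpec:
    return CPPProbeSpec(pulse_len=60, gaps=(60, 40, 20, 10, 0), lead_in=100)


@pytest.fixture(scope="session")
def default_sequence():
    """The full-scale training protocol used by the screening experiments."""
    return make_training_sequence(ProtocolSpec(), seed=42)


@pytest.fixture(scope="session")
def default_probe():
    return make_cpp_probe(CPPProbeSpec())


@pytest.fixture(scope="session")
def trained_default(default_sequence, default_probe):
    """One default-sized ESN trained on the standard protocol."""
    model = build_esn(ESNConfig(seed=1))
    record = run_esn(model, default_sequence.inputs)
    return train_readout(model, record, default_sequence.desired)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
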