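import numpy as np
import pytest

from neuroperf import (
    DetectorParams,
    DeviceGeometry,
    FlowSetup,
    FluidProperties,
    NeuronModel,
    Protocol,
    Segment,
)


@pytest.fixture
def geometry() -> DeviceGeometry:
    """The study device: 80 μm × 2 mm × 9.5 mm chambers."""
    return DeviceGeometry()


@pytest.fixture
def flow() -> FlowSetup:
    """Pump rates reproducing Q_Ch = 4 μl/min and HRT = 25 s."""
    return FlowSetup()


@pytest.fixture
def fluid() -> FluidProperties:
    """Water at room temperature with a small-molecule solute."""
    return FluidProperties()


@pytest.fixture
def detector() -> DetectorParams:
    return DetectorParams()


@pytest.fixture
def naive_chamber_protocol() -> Protocol:
    """5-min baseline + 5-min agonist segment at the naïve-chamber rates."""
    return Protocol(
        frame_rate=2.0,
        segments=(
            Segment(label="baseline", duration_s=300.0, spont_rate_per_min=0.16),
            Segment(
                label="drug",
                duration_s=300.0,
                compound="glutamate",
                concentration_M=3e-6,
                spont_rate_per_min=0.38,
            ),
        ),
    )


@pytest.fixture
def quiet_neuron() -> NeuronModel:
    """A neuron with spontaneous transients at 10× the frame-noise SD and no
    direct evoked response (naïve-chamber configuration)."""
    return NeuronModel(
        f0=100.0, noise_sd=2.0, spont_amplitude=20.0, resp_amplitude_max=0.0
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
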