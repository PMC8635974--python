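import numpy as np
import pytest

from retbias.fret import CorrectionCoefficients
from retbias.protocol import ApplicationEvent, ApplicationProtocol
from retbias.synthetic import FretGroundTruth


@pytest.fixture
def single_pulse_protocol():
    """One 30 s ACh pulse at 2 Hz with generous buffer on both sides."""
    return ApplicationProtocol(
        events=(ApplicationEvent("ACh", 3e-5, 60.0, 90.0),),
        total_duration=180.0,
    )


@pytest.fixture
def two_pulse_protocol():
    return ApplicationProtocol(
        events=(
            ApplicationEvent("ACh", 3e-5, 60.0, 90.0),
            ApplicationEvent("Pilo", 3e-5, 150.0, 180.0),
        ),
        total_duration=260.0,
    )


@pytest.fixture
def clean_truth():
    """Noiseless, bleach-free, cross-talk-free generator truth; fast on-rate
    so responses are fully developed inside the 5 s windows."""
    return FretGroundTruth(efficacies={"ACh": 1.0, "Pilo": 0.1}, on_rate=50.0)


@pytest.fixture
def dirty_truth():
    """Cross-talk, background and bleaching on; still noiseless."""
    return FretGroundTruth(
        efficacies={"ACh": 1.0, "Pilo": 0.1},
        on_rate=50.0,
        donor_bleach_rate=2e-4,
        acceptor_bleach_rate=4e-4,
        bleedthrough_frac=0.15,
        false_excitation_frac=0.05,
        background_donor=10.0,
        background_acceptor=8.0,
    )


@pytest.fixture
def dirty_coeff(dirty_truth):
    return CorrectionCoefficients(
        background_donor=dirty_truth.background_donor,
        background_acceptor=dirty_truth.background_acceptor,
        bleedthrough_frac=dirty_truth.bleedthrough_frac,
        false_excitation_frac=dirty_truth.false_excitation_frac,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
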