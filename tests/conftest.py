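import numpy as np
import pytest

from flimbind.decay import DecayModel
from flimbind.tcspc import AcquisitionConfig, IRFSpec, TCSPCDataset, periodic_decay_expectation


@pytest.fixture
def small_acq() -> AcquisitionConfig:
    """Coarse, low-count acquisition keeping unit-test fits fast."""
    return AcquisitionConfig(
        n_channels=1024,
        channel_width_ps=48.8,
        rep_period_ns=50.0,
        total_counts=1.0e6,
        background_fraction=1.0e-3,
        irf_total_counts=2.0e5,
    )


@pytest.fixture
def narrow_irf() -> IRFSpec:
    return IRFSpec(fwhm_ps=200.0, center_ns=2.0)


def make_noiseless_dataset(
    model: DecayModel, acq: AcquisitionConfig
) -> TCSPCDataset:
    """Rounded noiseless decay with a delta IRF in the first channel."""
    expected = periodic_decay_expectation(model, acq)
    irf = np.zeros(acq.n_channels, dtype=np.int64)
    irf[0] = 1_000_000
    return TCSPCDataset(
        channel_times_ns=acq.channel_times_ns,
        counts=np.round(expected).astype(np.int64),
        irf_counts=irf,
        acq=acq,
    )
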