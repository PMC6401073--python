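import numpy as np
import pytest

from iscmusic.synthetic import default_snr_table, simulate_segment_stacks


@pytest.fixture(scope="session")
def flat_snr():
    """SNR table with no condition effects (same scale in every cell)."""
    return default_snr_table(
        3,
        familiar_by_repeat=(1.0, 1.0, 1.0),
        unfamiliar_by_repeat=(1.0, 1.0, 1.0),
        distract_factor=1.0,
        training_scale={"trained": 1.0, "untrained": 1.0},
    )


@pytest.fixture(scope="session")
def small_study(flat_snr):
    """Clean 6-subject, 3-piece study with a strong planted component."""
    stacks, truth, meta = simulate_segment_stacks(
        n_subjects=6,
        n_pieces=3,
        n_repeats=2,
        duration_s=6.0,
        n_channels=8,
        k=2,
        signal_amp=20.0,
        component_scales=(1.0, 0.7),
        noise_sd=10.0,
        snr_by_cell=flat_snr,
        seed=11,
    )
    return stacks, truth, meta


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
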