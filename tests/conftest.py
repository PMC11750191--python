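import numpy as np
import pytest

from heartage import BeatParams, simulate_ecg_record


@pytest.fixture(scope="session")
def healthy_record():
    """One default healthy synthetic record plus its ground truth."""
    return simulate_ecg_record(BeatParams(seed=42))


@pytest.fixture(scope="session")
def noiseless_record():
    """Noise-free, jitter-free record: exact Kors round trips."""
    p = BeatParams(noise_sigma_uv=0.0, seed=7)
    return simulate_ecg_record(p, rr_jitter_frac=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
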