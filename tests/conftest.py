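import numpy as np
import pytest

from protogan import synthetic
from protogan.model import build_networks, init_latent_gmm
from protogan.preprocess import SegmentationConfig, bandpass_filter, cwt_scalogram, segment_signal


@pytest.fixture(scope="session")
def small_records():
    """A few short labeled synthetic signals (one window each)."""
    return synthetic.generate_dataset(n_total=15, duration=2.88, seed=11)


@pytest.fixture(scope="session")
def small_scalograms(small_records):
    """16x16 scalograms of the small synthetic set."""
    cfg = SegmentationConfig()
    out = []
    for rec in small_records:
        for seg in segment_signal(bandpass_filter(rec), cfg):
            out.append(cwt_scalogram(seg, out_size=16))
    return out


@pytest.fixture(scope="session")
def tiny_bundle():
    """A 16x16 model at an eighth of the full channel width."""
    return build_networks(image_size=16, dz=8, width_scale=0.125, seed=0)


@pytest.fixture(scope="session")
def tiny_gmm():
    return init_latent_gmm(3, dz=8, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
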