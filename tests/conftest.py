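import numpy as np
import pytest

from songseg.config import ClassDef, NetworkConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Small no-frontend network for fast structural tests."""
    return NetworkConfig(
        rate=2000.0,
        chunk_samples=512,
        channels=1,
        kernel_count=8,
        kernel_size=8,
        tcn_blocks=1,
        classes=[ClassDef("pulse", "event"), ClassDef("sine", "segment")],
    )


@pytest.fixture
def tiny_frontend_config():
    return NetworkConfig(
        rate=16000.0,
        chunk_samples=1024,
        channels=1,
        use_stft=True,
        stft_pairs=17,
        stft_duration_T=32,
        stft_stride_s=8,
        kernel_count=8,
        kernel_size=4,
        tcn_blocks=1,
        classes=[ClassDef("usv", "segment")],
    )
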