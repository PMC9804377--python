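import numpy as np
import pytest

from corrseg.nn import NetworkConfig
from corrseg.store import init_sync_directory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_net_config():
    """A miniature architecture for fast logic tests (same geometry rules)."""
    return NetworkConfig(down_widths=(4, 8, 12), up_widths=(8, 6),
                         input_size=92, output_size=20)


@pytest.fixture
def sync(tmp_path):
    return init_sync_directory(tmp_path / "sync")


@pytest.fixture
def small_dataset(sync, rng):
    """A dataset folder of five 96x96 grayscale PNGs."""
    from PIL import Image

    ds = sync.datasets / "tiny"
    ds.mkdir()
    for i in range(5):
        a = (rng.random((96, 96)) * 255).astype(np.uint8)
        Image.fromarray(a).save(ds / f"img_{i}.png")
    return ds
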