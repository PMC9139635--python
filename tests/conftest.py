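import numpy as np
import pytest

from buspool import PhantomConfig
from buspool.phantom import generate_frame


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_config():
    return PhantomConfig(frame_size=64, seed=0)


@pytest.fixture(scope="session")
def speckle_frames(phantom_config):
    """50 clean phantom frames (mixed classes) for metric property checks."""
    rng = np.random.default_rng(7)
    frames = []
    for i in range(50):
        label = "malignant" if i % 2 else "benign"
        frame, _ = generate_frame(phantom_config, label, rng)
        frames.append(frame.pixels)
    return frames


def make_micro_model(input_size: int = 32, seed: int = 0):
    """Smallest ConvNeXt that exercises all four stages (for fast tests)."""
    from buspool.convnext import ConvNeXt, ConvNeXtConfig

    cfg = ConvNeXtConfig(
        stage_depths=(1, 1, 1, 1),
        stage_widths=(4, 8, 12, 16),
        input_size=input_size,
    )
    return ConvNeXt(cfg, seed=seed)
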