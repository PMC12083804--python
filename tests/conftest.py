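import numpy as np
import pytest

from rscdnet.network import NetworkConfig
from rscdnet.synthetic_data import SyntheticSeedSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tiny_net_config(num_classes=2, input_size=64):
    """Scaled-down backbone: one block per stage, widths /8."""
    return NetworkConfig(
        num_classes=num_classes,
        stage_sizes=(1, 1, 1, 1),
        stage_mid_channels=(8, 16, 32, 64),
        stem_channels=8,
        input_size=input_size,
    )


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """2 classes x (8 train / 2 val / 2 test), 64 px, fixed master seed."""
    root = tmp_path_factory.mktemp("data") / "ds2"
    spec = SyntheticSeedSpec(num_classes=2, per_class=(8, 2, 2),
                             image_size=64, master_seed=5)
    generate_dataset(spec, root)
    return root, spec
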