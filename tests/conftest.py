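import numpy as np
import pytest

from nucseg import NetworkConfig, SceneConfig, build_network, generate_scene


@pytest.fixture(scope="session")
def tiny_config():
    return NetworkConfig(num_levels=2, base_width=4, dropout_p=0.5)


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    return build_network(tiny_config, seed=0)


@pytest.fixture(scope="session")
def small_image():
    return np.random.default_rng(42).random((3, 16, 16))


@pytest.fixture(scope="session")
def small_scene():
    return generate_scene(SceneConfig(height=32, width=32, n_nuclei=(3, 3),
                                      radius_range=(4.0, 6.0),
                                      min_center_distance=11.0),
                          seed=3)
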