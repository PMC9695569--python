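import pytest

from pspwedge import default_config
from pspwedge.config import build_profiles, geometry_from_config


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def geometry(config):
    return geometry_from_config(config)


@pytest.fixture(scope="session")
def profiles(config):
    return build_profiles(config)


@pytest.fixture(scope="session")
def express(profiles):
    return profiles["express_like"]


@pytest.fixture(scope="session")
def vistascan(profiles):
    return profiles["vistascan_like"]


@pytest.fixture(scope="session")
def small_config(config):
    """A scaled-down but structurally complete study: 2 systems x
    2 exposures x 3 light conditions x 2 repeats = 24 images."""
    return config.model_copy(update={
        "exposure_times_s": [0.10, 0.50],
        "light_durations_s": [0, 10, 90],
        "n_repeats": 2,
        "root_seed": 7,
    })
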