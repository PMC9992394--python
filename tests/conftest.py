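import numpy as np
import pytest

from olsenp.conversion import build_default_registry
from olsenp.synthetic import SyntheticConfig, generate_rasters, generate_samples


@pytest.fixture(scope="session")
def registry():
    return build_default_registry()


@pytest.fixture(scope="session")
def small_config():
    """Default-condition dataset, small n, with planted contamination."""
    return SyntheticConfig(
        seed=7, n_sites_per_country=100, sigma=0.3,
        stannous_fraction=0.02, volumetric_fraction=0.01,
        off_window_fraction=0.03, off_land_fraction=0.01,
        deep_only_fraction=0.02)


@pytest.fixture(scope="session")
def small_rasters(small_config):
    return generate_rasters(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_config, small_rasters):
    samples, manifest = generate_samples(small_config, small_rasters)
    return samples, manifest


@pytest.fixture(scope="session")
def clean_config():
    """Zero-noise, all-Olsen, contamination-free conditions (identity pipeline)."""
    return SyntheticConfig(
        seed=11, n_sites_per_country=60, sigma=0.0,
        method_mix={"olsen": 1.0, "bray1": 0.0, "mehlich3": 0.0,
                    "resin": 0.0, "kirsanov": 0.0, "abdpta": 0.0},
        censored_fraction=0.0, multilayer_fraction=0.0,
        exact_duplicate_fraction=0.0, coord_duplicate_fraction=0.0)


@pytest.fixture(scope="session")
def clean_dataset(clean_config):
    rasters = generate_rasters(clean_config)
    samples, manifest = generate_samples(clean_config, rasters)
    return samples, manifest, rasters


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
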