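"""Shared fixtures: tiny network configs and small synthetic site datasets."""

import numpy as np
import pytest

from fedseg import NetworkConfig
from fedseg.synthetic_data import SiteProfile, make_site_dataset


@pytest.fixture
def tiny_net() -> NetworkConfig:
    """Smallest practical U-Net: one level, two base channels."""
    return NetworkConfig(in_channels=1, base_channels=2, depth=1,
                         norm_kind="instance")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_tiny_sites(counts=(12, 8), image_size=(16, 16), base_seed=7):
    """Small heterogeneous sites for fast federation tests."""
    means = (0.85, 0.6, 0.75, 0.9)
    shifts = (0.15, 0.4, 0.25, 0.1)
    profiles = [
        SiteProfile(site_id=k, n_k=n, intensity_mean=means[k % 4],
                    intensity_shift=shifts[k % 4], noise_sd=0.03,
                    shape_family="ellipse", size_range=(3.0, 5.0),
                    image_size=image_size, seed=base_seed + k)
        for k, n in enumerate(counts)
    ]
    return [make_site_dataset(p) for p in profiles]


@pytest.fixture
def two_tiny_sites():
    return make_tiny_sites()
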