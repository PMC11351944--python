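"""Shared fixtures: tiny synthetic bundles and desk-scale configurations."""

import numpy as np
import pytest

from celseg import PhantomConfig, SamplingConfig, NetworkConfig, generate_scan


@pytest.fixture(scope="session")
def phantom_config():
    return PhantomConfig()


@pytest.fixture(scope="session")
def positive_bundle(phantom_config):
    """A CEL-positive synthetic scan (fixed seed)."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        b = generate_scan(phantom_config, rng)
        if b.has_cels:
            return b
    raise RuntimeError("no positive scan in 20 draws")  # pragma: no cover


@pytest.fixture(scope="session")
def negative_bundle(phantom_config):
    """A CEL-free synthetic scan (fixed seed)."""
    rng = np.random.default_rng(11)
    for _ in range(20):
        b = generate_scan(phantom_config, rng)
        if not b.has_cels:
            return b
    raise RuntimeError("no negative scan in 20 draws")  # pragma: no cover


@pytest.fixture(scope="session")
def tiny_sampling():
    """Desk-scale patch sizes: 24^3 initial crop, 16^3 final."""
    return SamplingConfig(patches_per_scan=8, initial_patch_mm=24, final_patch_mm=16)


@pytest.fixture(scope="session")
def tiny_network():
    """Width-reduced 3-level network for CPU tests."""
    return NetworkConfig(encoder_filters=(4, 8, 16), decoder_filters=(16, 8, 4))
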