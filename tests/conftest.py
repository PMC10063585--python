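"""Shared fixtures: small seeded synthetic datasets and fast training configs."""

import numpy as np
import pytest

from wsdmgc import (PhantomSpec, RunConfig, generate_feature_dataset,
                    generate_phantom_dataset, mask_labels)


@pytest.fixture(scope="session")
def fast_config() -> RunConfig:
    """A small, quick-to-train configuration for unit tests."""
    return RunConfig(epochs=60, warm_epochs=4, restarts=1, embed_dim=16,
                     hidden_dims=(32,), conv_channels=(4, 8),
                     max_total_iters=15, seed=0)


@pytest.fixture(scope="session")
def tiny_phantoms():
    """3 well-separated clusters x 30 phantom patches (16 px), fully labeled."""
    return generate_phantom_dataset(
        PhantomSpec(n_clusters=3, per_cluster=30, image_size=16,
                    separation=3.0, seed=11))


@pytest.fixture(scope="session")
def masked_tiny(tiny_phantoms):
    """The tiny phantom set with 20% of labels kept (weak supervision)."""
    return mask_labels(tiny_phantoms, 0.2, seed=5)


@pytest.fixture(scope="session")
def feature_clouds():
    """Two tight, far-apart Gaussian clouds in 4-D."""
    return generate_feature_dataset(n_clusters=2, per_cluster=30, dim=4,
                                    centre_spacing=10.0, noise_sd=0.1, seed=3)


@pytest.fixture(scope="session")
def trained_tiny(masked_tiny, fast_config):
    """Embedder fitted once on the tiny weakly labeled phantoms."""
    from wsdmgc import fit_embedder

    params, history = fit_embedder(masked_tiny, fast_config)
    return params, history


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
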