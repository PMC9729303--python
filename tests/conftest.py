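import numpy as np
import pytest

from capstrack.geometry import StateLabel
from capstrack.synthetic import PhantomConfig, render_dataset_arrays


@pytest.fixture(scope="session")
def tiny_config():
    return PhantomConfig.tiny()


@pytest.fixture(scope="session")
def closed_frames(tiny_config):
    """Small in-memory closed-capsule dataset shared across tests."""
    images, masks, manifest = render_dataset_arrays(
        tiny_config, {StateLabel.CLOSED: 20}, seed=42, with_masks=True)
    manifest.images = {r.path: im for r, im in zip(manifest, images)}
    return images, masks, manifest


@pytest.fixture(scope="session")
def mixed_manifest(tiny_config):
    """In-memory dataset with all three states."""
    counts = {StateLabel.CLOSED: 12, StateLabel.OPEN: 10, StateLabel.LOST: 8}
    images, manifest = render_dataset_arrays(tiny_config, counts, seed=7)
    manifest.images = {r.path: im for r, im in zip(manifest, images)}
    return manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
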