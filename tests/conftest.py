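import numpy as np
import pytest

from vqradiomics.network import NetworkConfig, VQSegNet
from vqradiomics.phantom import PhantomSpec, generate_phantoms
from vqradiomics.pipeline import AugmentFlags, TrainConfig, train_segmentation


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def tiny_phantom_spec(seed: int = 0, n: int = 3) -> PhantomSpec:
    """Small, fast phantoms: 32 x 32 slices, 6 slices per volume."""
    return PhantomSpec(
        n_volumes_per_class=n,
        slice_shape=(32, 32),
        n_slices=6,
        tumor_size_range=(4.0, 7.0),
        seed=seed,
    )


def tiny_net_config() -> NetworkConfig:
    """Two-level network for 32 x 32 slices (latent grid 16 x 16, K=8, D=4)."""
    return NetworkConfig(
        channels_in=4,
        n_labels=4,
        encoder_filters=(4, 8),
        decoder_filters=(8, 4),
        codebook_K=8,
        codebook_D=4,
        groupnorm_groups=4,
    )


@pytest.fixture(scope="session")
def tiny_phantoms():
    return generate_phantoms(tiny_phantom_spec())


@pytest.fixture(scope="session")
def tiny_trained():
    """A briefly trained tiny network plus its training volumes."""
    volumes = generate_phantoms(tiny_phantom_spec())
    cfg = TrainConfig(learning_rate=1e-3, batch_size=8, max_epochs=2, seed=0,
                      augmentations=AugmentFlags(hflip=False, rotate=False,
                                                 intensity_shift=False,
                                                 intensity_scale=False))
    net, history = train_segmentation(volumes, tiny_net_config(), cfg)
    return net, volumes, history


@pytest.fixture
def tiny_net():
    return VQSegNet(tiny_net_config(), seed=0)
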