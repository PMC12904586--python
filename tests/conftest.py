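import numpy as np
import pytest

from bialign import SyntheticSpec, TrainConfig, generate


@pytest.fixture(scope="session")
def small_dataset():
    """Two small, well-separated modalities with half the cells truly paired."""
    spec = SyntheticSpec(
        n_cells_1=120, n_cells_2=110, n_types=3,
        n_shared_features=40, n_private_features_1=10, n_private_features_2=10,
        noise_sd=0.3, type_separation=6.0, pairing_ratio=0.5, seed=11,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def tiny_train_config():
    return TrainConfig(latent_dim=6, hidden_widths=(16, 8), max_epochs=25,
                       early_stop_patience=25, batch_size_cells=48,
                       batch_size_features=32, learning_rate=1e-3, seed=3)


@pytest.fixture()
def rng(request):
    # deterministic but distinct stream per test (stable across processes)
    import zlib

    seed = zlib.crc32(request.node.name.encode()) % (2**31)
    return np.random.default_rng(seed)
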