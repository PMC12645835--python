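import numpy as np
import pytest

import demuxsig as dx


@pytest.fixture(scope="session")
def panel():
    return dx.default_panel()


@pytest.fixture(scope="session")
def pore_model():
    return dx.make_pore_model(3, seed=1)


@pytest.fixture(scope="session")
def tiny_sets(panel, pore_model):
    """A small, easy simulated dataset shared across tests."""
    params = dx.SimParams(noise_sd=0.1)
    return dx.generate_dataset(panel, pore_model, params, n_per_class=10,
                               split=(0.6, 0.2, 0.2), seed=11)


@pytest.fixture(scope="session")
def tiny_config():
    """A miniature but structurally complete model configuration."""
    return dx.ModelConfig(
        input_length=16,
        fusion_channels=(2, 3, 3),
        residual_channels=2,
        kernel_sizes=(3, 3, 3, 3),
        d_model=8,
        n_heads=2,
        n_transformer_layers=1,
        ff_dim=8,
        tcn_channels=6,
        tcn_kernel=3,
        tcn_dilations=(1, 2),
        dropout=0.0,
        n_classes=3,
        mlp_hidden=5,
    )


@pytest.fixture
def rng():
    return np.random.RandomState(0)


def random_signalset(n=6, n_classes=3, length=(30, 60), seed=0, labeled=True):
    """Random labeled signals of varying length."""
    r = np.random.RandomState(seed)
    sigs = []
    for i in range(n):
        L = r.randint(length[0], length[1] + 1)
        sigs.append(dx.RawSignal(
            read_id=f"r{i}",
            samples=r.randn(L),
            label=int(r.randint(n_classes)) if labeled else None,
        ))
    return dx.SignalSet(signals=sigs, n_classes=n_classes)
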