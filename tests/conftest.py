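import numpy as np
import pytest

from mstnn.architecture import ArchitectureSpec, Layer, validate_architecture


def tiny_spec(tau1=2.0, tau2=5.0, pool=True, n_classes=3, head_reads="activation"):
    """A small two-conv-layer stack on 8x9 frames for fast exact tests."""
    layers = [
        Layer("input", 1, 8, 9),
        Layer("convolutional", 2, 6, 6, kernel=(3, 4), tau=tau1),
    ]
    if pool:
        layers += [
            Layer("max_pooling", 2, 3, 3, pool=2),
            Layer("convolutional", 3, 2, 2, kernel=(2, 2), tau=tau2),
        ]
    else:
        layers.append(Layer("convolutional", 3, 4, 4, kernel=(3, 3), tau=tau2))
    layers.append(Layer("fully_connected", classes=n_classes))
    return validate_architecture(ArchitectureSpec(tuple(layers), head_reads=head_reads))


@pytest.fixture
def small_spec():
    return tiny_spec()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
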