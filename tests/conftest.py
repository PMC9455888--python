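"""Shared fixtures: trained networks are expensive, so they are built once
per session and reused by every test that inspects them."""

import numpy as np
import pytest

from osnef.learning import LearningConfig


@pytest.fixture(scope="session")
def lif_identity_net():
    from osnef.networks import build_and_train_feedforward

    return build_and_train_feedforward(
        "identity", "lif", n=100, seed=0,
        cfg=LearningConfig(duration=100.0), optimize_readout=0)


@pytest.fixture(scope="session")
def lif_product_net():
    from osnef.networks import build_and_train_feedforward

    return build_and_train_feedforward(
        "product", "lif", n=100, seed=0,
        cfg=LearningConfig(duration=100.0), optimize_readout=0)


@pytest.fixture(scope="session")
def lif_oscillator_net():
    from osnef.networks import build_and_train_recurrent, oscillator_dynamics

    return build_and_train_recurrent(
        oscillator_dynamics(), "lif", n=100, seed=0,
        cfg=LearningConfig(duration=100.0))


@pytest.fixture(scope="session")
def lif_memory_net():
    from osnef.networks import build_gated_memory

    return build_gated_memory("lif", n=200, seed=0, n_pre=150,
                              cfg=LearningConfig(duration=80.0))
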