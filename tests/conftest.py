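"""Shared fixtures: small synthetic datasets and a cheaply trained model.

Everything is generated programmatically and seeded; session scope keeps
network training out of per-test cost.
"""

import numpy as np
import pytest

from idaod import (
    AutoencoderConfig,
    FineTuneConfig,
    LabeledDataset,
    SimulationConfig,
    featurize_dataset,
    fine_tune,
    pretrain_autoencoder,
    simulate_dataset,
)
from idaod.features import apply_feature_scale, fit_feature_scale


@pytest.fixture(scope="session")
def small_sim():
    """80 sequences (20 positive / 60 negative) with a strong planted bias."""
    return simulate_dataset(
        SimulationConfig(
            n_positive=20,
            n_negative=60,
            length_range=(50, 150),
            bias_strength=8.0,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def small_features(small_sim):
    X, ids = featurize_dataset(small_sim.records)
    scale = fit_feature_scale(X)
    return apply_feature_scale(X, scale), ids, small_sim.labels


@pytest.fixture(scope="session")
def small_dataset(small_features):
    X, ids, y = small_features
    return LabeledDataset(features=X, labels=y, ids=ids)


@pytest.fixture(scope="session")
def tiny_trained_model(small_dataset):
    """Encoder pre-trained 5 epochs, fine-tuned 10 — enough for contracts."""
    ae_cfg = AutoencoderConfig(epochs=5, seed=13)
    encoder, ae_losses = pretrain_autoencoder(small_dataset, ae_cfg)
    ft_cfg = FineTuneConfig(epochs=10, seed=13)
    model = fine_tune(encoder, small_dataset, ft_cfg,
                      ae_config=ae_cfg, pretrain_losses=ae_losses)
    return model


@pytest.fixture(scope="session")
def strong_representation(small_features):
    """A 50-dim representation trained to convergence on the planted-bias
    data; at small n this needs many epochs (few updates per epoch)."""
    from idaod import extract_representation

    X, ids, y = small_features
    data = LabeledDataset(features=X, labels=y)
    encoder, _ = pretrain_autoencoder(data, AutoencoderConfig(epochs=20, seed=13))
    model = fine_tune(encoder, data, FineTuneConfig(epochs=500, seed=13))
    return extract_representation(model, X), y


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
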