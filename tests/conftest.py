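"""Shared fixtures.

The expensive artifact — a feature extractor contrastively trained on a
4-class synthetic texture set — is built once per session and reused by the
representation, clustering, integration and classifier tests.
"""

import numpy as np
import pytest

from mixture import synthetic_cohort as synth
from mixture import ssl_encoder as ssl


N_PER_CLASS = 500
TILE = 32


def _texture_bank(n_per_class=N_PER_CLASS, seed=0):
    classes = synth.default_texture_classes(4)
    rng = np.random.default_rng(seed)
    tiles, labels = [], []
    for c in classes:
        for _ in range(n_per_class):
            tiles.append(synth.make_texture(c, TILE, seed=int(rng.integers(2**31))))
            labels.append(c.class_id)
    order = rng.permutation(len(tiles))
    return (np.stack(tiles)[order], np.asarray(labels)[order], classes)


@pytest.fixture(scope="session")
def texture_bank():
    """2000 pure-texture tiles (4 classes x 500), shuffled, with labels."""
    return _texture_bank()


@pytest.fixture(scope="session")
def ssl_config():
    return ssl.SSLConfig(queue_size=256, crop_size=TILE, input_size=32,
                         epochs=10, batch_size=64, seed=11)


@pytest.fixture(scope="session")
def trained_encoder(texture_bank, ssl_config):
    """ElEx trained 10 epochs on the texture bank (the shared slow step)."""
    tiles, _, _ = texture_bank
    return ssl.train_elex(tiles, ssl_config)


@pytest.fixture(scope="session")
def untrained_encoder(texture_bank, ssl_config):
    import dataclasses
    cfg = dataclasses.replace(ssl_config, epochs=0)
    tiles, _, _ = texture_bank
    return ssl.train_elex(tiles, cfg)


@pytest.fixture(scope="session")
def texture_features(trained_encoder, texture_bank):
    tiles, _, _ = texture_bank
    return trained_encoder.embed(tiles)
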