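"""Shared fixtures: synthetic slides and a session-scoped trained model."""

import numpy as np
import pytest

from histoseg import classifier, patches, synthetic


@pytest.fixture(scope="session")
def small_spec():
    return synthetic.SyntheticSpec(image_width=640, image_height=640,
                                   region_layout_seed=7, rng_seed=7)


@pytest.fixture(scope="session")
def small_sample(small_spec):
    return synthetic.generate_tissue_sample(small_spec)


@pytest.fixture(scope="session")
def plaque_free_sample():
    spec = synthetic.SyntheticSpec(
        image_width=640, image_height=640, region_layout_seed=3, rng_seed=3,
        plaque_rates={})
    return synthetic.generate_tissue_sample(spec)


def train_tiny_model(sample, seed=0, n_patches=450, max_epochs=6):
    pool = patches.sample_training_patches(sample, n=n_patches, size=256,
                                           seed=seed)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    cut = int(0.8 * len(pool))
    train = [pool[i] for i in order[:cut]]
    val = [pool[i] for i in order[cut:]]
    cfg = classifier.TrainConfig(max_epochs=max_epochs, seed=seed)
    model, log = classifier.train_classifier(train, val, cfg)
    return model, log, val


@pytest.fixture(scope="session")
def trained_model(small_sample):
    model, log, val = train_tiny_model(small_sample)
    return model


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
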