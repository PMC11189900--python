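"""Shared fixtures.

The trained convolutional predictor is expensive (tens of thousands of
training sequences), so it is built once per session and shared by the
design- and generation-level tests that score against it.
"""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from utrforge.predictors import CNNSpec, ConvolutionalMRLRegression, evaluate_r2
from utrforge.synthetic import GroundTruthParams, generate_library, ground_truth_mrl_batch


@pytest.fixture(scope="session")
def planted_training_data():
    """30,000 training + 1,000 validation + 1,000 test sequences with
    noisy planted MRLs (observation noise sigma = 0.3)."""
    params = GroundTruthParams(noise_sigma=0.3)
    records = generate_library(32_000, seed=101)
    noisy = ground_truth_mrl_batch(records, params, noise_seed=102)
    clean = ground_truth_mrl_batch(records, params)
    seqs = [r.sequence for r in records]
    return {
        "params": params,
        "train": (seqs[:30_000], noisy[:30_000]),
        "val": (seqs[30_000:31_000], noisy[30_000:31_000]),
        "test": (seqs[31_000:], noisy[31_000:]),
        "test_clean": clean[31_000:],
    }


@pytest.fixture(scope="session")
def trained_cnn(planted_training_data):
    d = planted_training_data
    model = ConvolutionalMRLRegression(*d["train"], *d["val"], spec=CNNSpec())
    return model.fit(max_epochs=10, patience=3, seed=103)


@pytest.fixture(scope="session")
def random_pool_scores(trained_cnn):
    """Predictor scores of 10,000 random 25nt sequences (design baselines)."""
    pool = generate_library(10_000, seed=104)
    return trained_cnn.predict([r.sequence for r in pool])
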