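"""Shared fixtures: a fixture-trained polynomial model and a planted batch.

Session-scoped because SVR training and batch generation dominate runtime;
everything is deterministic (fixed seeds), so sharing cannot couple tests.
"""

import pytest

from ptaref import fixtures
from ptaref.pipeline import PipelineConfig
from ptaref.svr_model import SVRConfig, train

TRAIN_SEED = 101
BATCH_SEED = 202
LIBRARY_SEED = 303


@pytest.fixture(scope="session")
def site_training_set():
    return fixtures.make_site_training_set(n_pos=150, n_neg=150, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def polynomial_model(site_training_set):
    pos, neg = site_training_set
    return train(pos, neg, SVRConfig(kernel="polynomial"))


@pytest.fixture(scope="session")
def planted_batch():
    """50 transcripts, one planted site each, against a 3-miRNA panel."""
    return fixtures.make_planted_batch(50, n_mirnas=3, seed=BATCH_SEED)


@pytest.fixture(scope="session")
def pattern_library():
    return fixtures.make_pattern_library(20, seed=LIBRARY_SEED)


@pytest.fixture()
def pipeline_config():
    return PipelineConfig(threads=1)
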