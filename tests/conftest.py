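"""Shared fixtures: a small seeded dataset and a trained template database.

Everything is generated at test time from the synthetic module; nothing is
read from disk.  The small dataset (2 x 2 min training, 1 x 2 min
evaluation, 2 events/min) keeps per-test cost low while still producing a
database with a few dozen templates.
"""

from __future__ import annotations

import numpy as np
import pytest

from iedreview.eeg_io import preprocess
from iedreview.synthetic import DatasetSpec, make_dataset
from iedreview.template_db import extract_templates, prune, train_templates

SMALL_SPEC = DatasetSpec(n_train=2, n_eval=1, duration_s=120.0, rate_per_min=2.0)
SMALL_SEED = 11


@pytest.fixture(scope="session")
def small_dataset():
    return make_dataset(SMALL_SPEC, seed=SMALL_SEED)


@pytest.fixture(scope="session")
def preprocessed_training(small_dataset):
    train_recs, train_anns, _, _ = small_dataset
    return [preprocess(r) for r in train_recs], train_anns


@pytest.fixture(scope="session")
def extracted_templates(preprocessed_training):
    recs, anns = preprocessed_training
    return extract_templates(recs, anns)


@pytest.fixture(scope="session")
def trained_db_unpruned(extracted_templates, preprocessed_training):
    recs, anns = preprocessed_training
    # templates are mutated by training; train on copies so fixtures stay pure
    import copy

    return train_templates(copy.deepcopy(extracted_templates), recs, anns)


@pytest.fixture(scope="session")
def trained_db(trained_db_unpruned):
    return prune(trained_db_unpruned)


@pytest.fixture(scope="session")
def eval_recording(small_dataset):
    _, _, eval_recs, eval_truths = small_dataset
    return preprocess(eval_recs[0]), eval_truths[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
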