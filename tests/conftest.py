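"""Shared fixtures: synthetic cohorts and trained models.

Training a model is the expensive step, so trained models are
session-scoped and shared across the evaluation, explanation and
permutation tests.  Cohort sizes are kept moderate (300 patients) to keep
the default test run fast while preserving the planted-signal structure.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from iwsrisk import cohort as coh
from iwsrisk import features as feat
from iwsrisk import model as mdl

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("suite")

FIT_CONFIG = mdl.TrainConfig(max_epochs=400, patience=60, seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-patient default cohort for pipeline-level tests."""
    cfg = coh.CohortConfig(n_patients=40)
    timelines, gt = coh.generate_cohort(cfg, seed=7)
    return cfg, timelines, gt


@pytest.fixture(scope="session")
def small_prepared(small_cohort):
    _, timelines, _ = small_cohort
    return feat.prepare_cohort(timelines, seed=7)


@pytest.fixture(scope="session")
def strong_cohort():
    """The reference strong-signal cohort (dominant withdrawal-history term)."""
    cfg = coh.CohortConfig(n_patients=500)
    timelines, gt = coh.generate_cohort(cfg, seed=3)
    return cfg, timelines, gt


@pytest.fixture(scope="session")
def strong_prepared(strong_cohort):
    _, timelines, _ = strong_cohort
    return feat.prepare_cohort(timelines, seed=3)


@pytest.fixture(scope="session")
def strong_model(strong_prepared):
    p = strong_prepared
    params, history = mdl.train(p.train.X, p.train.y, p.val.X, p.val.y, FIT_CONFIG)
    return params, history


@pytest.fixture(scope="session")
def recency_cohort():
    """Cohort whose planted signal lives only in the most recent epoch."""
    cfg = coh.recency_config(n_patients=300)
    timelines, gt = coh.generate_cohort(cfg, seed=2)
    return cfg, timelines, gt


@pytest.fixture(scope="session")
def recency_prepared(recency_cohort):
    _, timelines, _ = recency_cohort
    return feat.prepare_cohort(timelines, seed=2)


@pytest.fixture(scope="session")
def recency_model(recency_prepared):
    p = recency_prepared
    params, history = mdl.train(p.train.X, p.train.y, p.val.X, p.val.y, FIT_CONFIG)
    return params, history


@pytest.fixture
def rng():
    return np.random.default_rng(0)
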