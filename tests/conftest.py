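"""Shared fixtures: synthetic sessions and the (expensive) fitted models."""

from __future__ import annotations

import numpy as np
import pytest

from vrsense.simulate import (
    SessionSpec,
    make_fixture_session,
    regime_recovery_benchmark,
    sample_hmm_benchmark,
    simulate_session,
)
from vrsense.stress import fit_hmm


@pytest.fixture(scope="session")
def tiny_session_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("tiny")
    paths = make_fixture_session("tiny", out)
    return paths


@pytest.fixture(scope="session")
def paperlike_session():
    """In-memory 10-subject session with ground truth (seed 0)."""
    return simulate_session(SessionSpec())


@pytest.fixture(scope="session")
def end_to_end_recovery_fit():
    """Stress HMM fitted on trajectory-derived features at session scale.

    600 windows over 10 subjects, the generator's default seed; returns the
    fitted model together with the feature sequences and true regimes.
    """
    sequences, truths, spec = regime_recovery_benchmark(n_windows=600, seed=0)
    model = fit_hmm(sequences, seed=0, n_init=10)
    return model, sequences, truths


@pytest.fixture(scope="session")
def known_model_recovery_fit():
    """Stress HMM fitted on 5,000 windows sampled from a known 6-state model."""
    sequences, truths, true_means = sample_hmm_benchmark(n_windows=5000, seed=0)
    model = fit_hmm(sequences, seed=0, n_init=10)
    return model, sequences, truths, true_means


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
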