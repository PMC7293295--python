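"""Shared fixtures: small synthetic recordings and cohorts, toy embeddings."""
import warnings

import numpy as np
import pytest

from pdvoice.audio import AudioRecording
from pdvoice.semantics import EmbeddingTable
from pdvoice.synth import (
    SyntheticCohortConfig,
    default_vocabulary,
    generate_toy_embeddings,
    synthesize_utterance,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def burst_recording():
    """5 s, 3 syllables/s, no pauses, deterministic intervals."""
    rec, truth = synthesize_utterance(
        5.0, 3.0, rng=np.random.default_rng(7), interval_jitter=0.0
    )
    return rec, truth


@pytest.fixture
def paused_recording():
    """5 s utterance with spliced-in 0.5 s silences."""
    rec, truth = synthesize_utterance(
        5.0, 3.0, pause_spec=(12.0, 0.5), rng=np.random.default_rng(8)
    )
    return rec, truth


@pytest.fixture(scope="session")
def toy_embeddings():
    return generate_toy_embeddings(default_vocabulary(), 16, np.random.default_rng(3))


@pytest.fixture
def silence():
    return AudioRecording(np.zeros(44100), 44100)


@pytest.fixture(scope="session")
def tiny_cohort_table():
    """Feature table of a 6-subject strong-effect cohort with short recordings."""
    from pdvoice.pipeline import RunConfig, extract_feature_table

    cfg = RunConfig(
        mode="synthetic",
        cohort=SyntheticCohortConfig(
            n_subjects=6, rng_seed=42, duration_s=6.0, ddk_duration_s=4.0
        ),
        seed=42,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return extract_feature_table(cfg)
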