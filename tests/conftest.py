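import numpy as np
import pytest

import clearclip as cc
from clearclip.config import SimulationConfig


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_reads=5_000, rng_seed=42)


@pytest.fixture(scope="session")
def small_study(small_config):
    """Reference + planted truth shared across test modules (read-only)."""
    ref = cc.generate_reference(small_config)
    truth = cc.plant_interactions(ref, small_config)
    return ref, truth


@pytest.fixture(scope="session")
def small_library(small_study, small_config):
    ref, truth = small_study
    records, labels = cc.simulate_library(ref, truth, small_config, "120hPE")
    return records, labels


@pytest.fixture(scope="session")
def classifier(small_study):
    ref, _ = small_study
    return cc.Classifier(ref.mirnas, ref.transcripts, ref.annotation)


@pytest.fixture(scope="session")
def classified_library(small_library, classifier):
    """Prep + classification of the shared 5k-read library."""
    records, labels = small_library
    reads = [cc.ReadRecord(rid, seq, [37] * len(seq)) for rid, seq, _ in records]
    kept, stats = cc.prepare_reads(reads)
    chim, clip_df, counts, weighted = classifier.classify_reads(kept)
    return dict(
        kept=kept, stats=stats, chim=chim, clip=clip_df, counts=counts,
        weighted=weighted, labels=labels,
    )


@pytest.fixture()
def rng():
    return np.random.Generator(np.random.PCG64(7))
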