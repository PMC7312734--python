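import numpy as np
import pytest

import ppiwave as pw
from ppiwave.pairs import build_pair_feature


@pytest.fixture(scope="session")
def table():
    return pw.default_property_table()


@pytest.fixture(scope="session")
def synthetic_dataset():
    """60 archetype proteins with their 600-dim descriptors (seeded)."""
    cfg = pw.SyntheticConfig(seed=7)
    records, archetypes, _ = pw.generate_sequences(cfg)
    features = {pid: pw.featurize_protein(seq, protein_id=pid)
                for pid, seq in records}
    return records, archetypes, features


@pytest.fixture(scope="session")
def planted_pairs(synthetic_dataset):
    """400 noiseless planted pairs as PairFeature records."""
    _, archetypes, features = synthetic_dataset
    pair_records = pw.generate_labels(archetypes, 400, 0.5, 0.0, seed=7)
    return [build_pair_feature(features[p.id_a], features[p.id_b], p.label)
            for p in pair_records]


@pytest.fixture(scope="session")
def learnability_config():
    """Reduced-width training configuration used for desk-scale runs."""
    return pw.ModelConfig(
        rnn_units=32, buffer_units=16, dense_units=(16, 8, 2),
        batch_size=128, learning_rate=0.05, momentum=0.9, epochs=30, seed=7,
    )


@pytest.fixture
def tiny_config():
    """Smallest valid architecture, for fast structural tests."""
    return pw.ModelConfig(
        rnn_units=8, buffer_units=8, dense_units=(8, 2),
        batch_size=16, epochs=2, seed=3,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
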