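import numpy as np
import pytest

from memtopo import seqio, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_record():
    return seqio.SequenceRecord(id="p1", residues="MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")


@pytest.fixture
def small_profile(small_record):
    return seqio.pseudo_profile(small_record)


@pytest.fixture(scope="session")
def tiny_corpus():
    cfg = synthetic.TopologyGeneratorConfig(n_proteins=12, seed=11)
    return synthetic.generate_membrane_protein_corpus(cfg)


def random_profile(rng, L, record_id="rnd"):
    raw = rng.normal(0.0, 2.0, size=(L, 20))
    return seqio.Profile(record_id=record_id, raw=raw)
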