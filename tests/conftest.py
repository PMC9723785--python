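import pytest

from protoscribe.config import ThresholdConfig
from protoscribe.fixtures import make_genome, make_reference_set, mutate, write_fixture_bundle
from protoscribe.seqio import SequenceRecord

SEED = 1234


@pytest.fixture(scope="session")
def cfg():
    return ThresholdConfig()


@pytest.fixture(scope="session")
def reference_set():
    return make_reference_set(n_entries=60, seed=SEED)


@pytest.fixture(scope="session")
def query_16s(reference_set):
    """A near-identical relative of the first reference (known species)."""
    base = SequenceRecord(id="query_16s", seq=reference_set[0].seq)
    mutant, _ = mutate(base, 0.005, seed=SEED, stream="query16s")
    return SequenceRecord(id="query_16s", seq=mutant.seq)


@pytest.fixture(scope="session")
def genome_50k():
    return make_genome(50_000, 0.489, SEED, stream="test_genome", id="g50k")


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    write_fixture_bundle(out, seed=SEED)
    return out
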