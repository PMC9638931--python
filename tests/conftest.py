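import pytest

from pemseq import SeedIndex, build_toy_reference


@pytest.fixture(scope="session")
def toy():
    """The default desk-scale reference: 2 x 2 Mb chromosomes, cut at chr1:1e6,
    2.8 kb vector with identical 400 bp LTRs."""
    return build_toy_reference()


@pytest.fixture(scope="session")
def ref(toy):
    return toy[0]


@pytest.fixture(scope="session")
def target(toy):
    return toy[1]


@pytest.fixture(scope="session")
def genes(toy):
    return toy[2]


@pytest.fixture(scope="session")
def seed_index(ref):
    """Session-wide 20-mer index over genome + vector (built once; ~8 s)."""
    return SeedIndex(ref)
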