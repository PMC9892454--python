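import pytest

from chiprx.simulate import TruthTable, build_genome


@pytest.fixture(scope="session")
def small_genome():
    """One 1 Mb chromosome, 10 genes, 5 enhancers, 1 spike chromosome."""
    return build_genome(1, 1_000_000, 10, 5, 1, seed=1)


@pytest.fixture()
def neutral_truth():
    return TruthTable()
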