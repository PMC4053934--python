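import pytest

from parclip import align_unique, collapse_duplicates, make_scenario


@pytest.fixture(scope="session")
def scenario():
    """Small end-to-end scenario with planted sites (8 sites, 10 genes)."""
    return make_scenario(seed=11, genome_length=20_000, n_genes=10)


@pytest.fixture(scope="session")
def aligned(scenario):
    collapsed = collapse_duplicates(scenario.reads)
    reads, stats = align_unique(collapsed, scenario.genome)
    return reads, stats
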