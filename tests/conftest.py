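import pytest

from fusegraph import build_graph, skbr3


@pytest.fixture(scope="session")
def catalog():
    """Parsed SK-BR-3 fusion catalog: pair -> list of BreakpointPath."""
    return skbr3.catalog_paths()


@pytest.fixture(scope="session")
def catalog_alleles(catalog):
    return [p for paths in catalog.values() for p in paths]


@pytest.fixture()
def bundle_graph():
    """Breakpoint graph over the SK-BR-3 worked-example call set."""
    return build_graph(skbr3.gsr_calls(), skbr3.gene_models())
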