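import pytest

from nextgene import GeneRecord, MethodTerm, build_term_index
from nextgene.simulate import SimConfig, generate_world

PLK1_SENTENCE = "Inhibition of Plk1 suppressed loss of HsSAS6 from the centrioles."


@pytest.fixture(scope="session")
def toy_genes():
    return [
        GeneRecord(symbol="PLK1", aliases=frozenset({"Plk1"})),
        GeneRecord(symbol="SASS6", aliases=frozenset({"HsSAS6", "SAS6"})),
        GeneRecord(symbol="TP53", aliases=frozenset({"p53"})),
    ]


@pytest.fixture(scope="session")
def toy_methods():
    return [
        MethodTerm(name="inhibition", category="knockdown/knockout"),
        MethodTerm(name="immunostaining", category="immunofluorescence"),
    ]


@pytest.fixture(scope="session")
def toy_index(toy_genes, toy_methods):
    return build_term_index(toy_genes, toy_methods, min_length=3)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_genes=60,
        n_modules=6,
        n_articles=80,
        profile_length=30,
        embedding_dim=24,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    return generate_world(small_config)
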