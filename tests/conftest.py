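import pytest

from moarx import DiseaseClassMap, EnginePolicy
from moarx.examples import example_text, example_kb


@pytest.fixture(scope="session")
def cancer_map():
    return DiseaseClassMap()


@pytest.fixture(scope="session")
def default_policy():
    return EnginePolicy()


@pytest.fixture(scope="session")
def dipyridamole_kb():
    return example_kb("dipyridamole")


@pytest.fixture(scope="session")
def tazarotene_kb():
    return example_kb("tazarotene")


@pytest.fixture(scope="session")
def cladribine_kb():
    return example_kb("cladribine")


@pytest.fixture(scope="session")
def merged_examples_kb():
    """Both worked-example fact sets in one knowledge base."""
    from moarx import parse_fact_file

    return parse_fact_file(example_text("dipyridamole") + example_text("tazarotene"))
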