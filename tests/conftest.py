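import pytest

from herbrel import examples_data as D
from herbrel.corpus_io import parse_document
from herbrel.lexicon import build_mpc_property, build_mpc_symptom, merge_dedupe


@pytest.fixture(scope="session")
def thai_ws():
    return D.thai_word_sets()


@pytest.fixture(scope="session")
def thai_mpc(thai_ws):
    return merge_dedupe(
        build_mpc_property(D.property_lexicon(), thai_ws),
        build_mpc_symptom(D.symptom_lexicon(), thai_ws),
    )


@pytest.fixture(scope="session")
def basil_doc():
    return parse_document(D.BASIL_DOCUMENT_TEXT)
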