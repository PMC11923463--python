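import numpy as np
import pytest

from drugpulse import synthetic
from drugpulse.entities import LexiconEntry, build_matcher
from drugpulse.synthetic import EntitySpec, GeneratorConfig


@pytest.fixture
def small_lexicon():
    return [
        LexiconEntry("hcq", "hydroxychloroquine", "drug"),
        LexiconEntry("hydroxychloroquine", "hydroxychloroquine", "drug", "P"),
        LexiconEntry("zinc", "zinc", "drug", "A"),
        LexiconEntry("vitamin d", "vitamin d", "drug", "A"),
        LexiconEntry("vitamin", "multivitamin", "drug"),
        LexiconEntry("ivermectin", "ivermectin", "drug", "P"),
        LexiconEntry("fever", "fever", "symptom"),
        LexiconEntry("chest cold", "chest cold", "symptom"),
    ]


@pytest.fixture
def matcher(small_lexicon):
    return build_matcher(small_lexicon)


@pytest.fixture
def basic_entities():
    return (
        EntitySpec("zinc", ("zinc", "zn"), "drug", 0.15, "A"),
        EntitySpec("ivermectin", ("ivermectin", "ivm"), "drug", 0.10, "P"),
        EntitySpec("fever", ("fever",), "symptom", 0.12),
    )


@pytest.fixture
def basic_config(basic_entities):
    return GeneratorConfig(
        n_tweets=400,
        vocabulary_size=120,
        n_topics=3,
        entities=basic_entities,
        sentiment_profile={
            "zinc": (0.6, 0.3, 0.1),
            "ivermectin": (0.2, 0.3, 0.5),
            "fever": (0.0, 1.0, 0.0),
        },
        url_fraction=0.2,
        seed=11,
    )


@pytest.fixture
def basic_corpus(basic_config):
    return synthetic.generate(basic_config)


def lda_corpus_from_truth(truth, doc_ids=None):
    """TokenizedCorpus over generator token ids (bypasses text tokenizing)."""
    from drugpulse import lda

    docs = [[f"w{int(i):04d}" for i in d] for d in truth.doc_tokens]
    return lda.from_token_lists(docs)
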