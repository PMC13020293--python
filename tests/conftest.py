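import numpy as np
import pytest
from hypothesis import settings

import litmap as lm
from litmap.topic_model import HDBSCANClusterer, PCAReducer

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def corpus_spec() -> lm.CorpusSpec:
    return lm.CorpusSpec(n_topics=2, docs_per_topic=30, topic_vocab_overlap=0.1, seed=7)


@pytest.fixture(scope="session")
def synthetic_corpus(corpus_spec):
    xml, manifest = lm.generate_corpus(corpus_spec)
    return xml, manifest


@pytest.fixture(scope="session")
def records(synthetic_corpus):
    xml, _ = synthetic_corpus
    return lm.parse_pubmed_xml(xml)


@pytest.fixture(scope="session")
def embedder():
    return lm.HashingEmbedder(dim=128, seed=1)


@pytest.fixture(scope="session")
def doc_vectors(records, embedder):
    return lm.embed_corpus(records, embedder)


@pytest.fixture(scope="session")
def fitted_model(doc_vectors):
    vectors, pub_ids = doc_vectors
    return lm.fit_topic_model(
        vectors,
        pub_ids=pub_ids,
        reducer=PCAReducer(),
        clusterer=HDBSCANClusterer(min_cluster_size=5),
        seed=0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
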