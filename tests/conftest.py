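import numpy as np
import pytest

from metaret.corpus_io import DatasetDoc, RawQuery, SampledQrels
from metaret.indexer import Stoplist, build_index
from metaret.synthetic import SynthConfig, generate


@pytest.fixture()
def tiny_docs():
    return [
        DatasetDoc("d1", "gene gene disease", "the gene is studied"),
        DatasetDoc("d2", "disease", "another disease description"),
    ]


@pytest.fixture()
def tiny_indices(tiny_docs):
    return build_index(tiny_docs, Stoplist.empty())


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(n_docs=400, n_topics=2, background_vocab=100,
                       topic_vocab=80, n_synonym_families=4, doc_len_mean=60,
                       n_queries=4, grade2_per_query=6, grade1_per_query=5,
                       judged_nonrel_per_query=10, seed=11)


@pytest.fixture(scope="session")
def small_coll(small_config):
    return generate(small_config)


def random_corpus(rng: np.random.Generator, n_docs: int = 25,
                  vocab: int = 30, doc_len: int = 20) -> list[DatasetDoc]:
    """A small random corpus for reduction/oracle tests."""
    words = [f"v{i}" for i in range(vocab)]
    docs = []
    for i in range(n_docs):
        title = " ".join(rng.choice(words, size=max(2, doc_len // 4)))
        body = " ".join(rng.choice(words, size=doc_len))
        docs.append(DatasetDoc(f"d{i}", title, body))
    return docs


def random_query(rng: np.random.Generator, vocab: int = 30,
                 n_terms: int = 3) -> RawQuery:
    words = rng.choice([f"v{i}" for i in range(vocab)], size=n_terms,
                       replace=False)
    return RawQuery("q0", " ".join(words))


def random_qrels(rng: np.random.Generator, query_id: str = "q",
                 n_docs: int = 100, n_judged: int = 40) -> SampledQrels:
    judged = rng.choice(n_docs, size=n_judged, replace=False)
    judgments = {(query_id, f"d{i}"): int(rng.choice([0, 0, 1, 2]))
                 for i in judged}
    return SampledQrels(judgments=judgments)
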