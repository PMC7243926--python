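"""Skip-gram-with-negative-sampling embeddings and query expansion.

The trainer is a self-contained SGNS implementation (numba-accelerated SGD
over a merged title+description token stream) optimizing

    log sigmoid(w'c) + k * E_{c~P_D}[log sigmoid(-w'c)]

with the negative-sampling distribution P_D proportional to unigram
frequency^0.75.  Each extracted medical entity word seeds an expansion with
its five cosine-nearest vocabulary terms at weight 0.1; original query
terms keep weight 0.9.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from metaret.corpus_io import DatasetDoc, RawQuery
from metaret.indexer import Stoplist, preprocess

logger = logging.getLogger(__name__)

# corpus-building tokenizer: lowercase, *all* punctuation (hyphens included)
# acts as a separator; digit/letter runs stay together ("il2" is one token)
W2V_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


def w2v_tokenize(text: str) -> list[str]:
    return W2V_TOKEN_RE.findall(text.lower())


def build_training_corpus(docs: Iterable[DatasetDoc]) -> list[str]:
    """Merged token stream over every doc's title + description.

    Lowercased, punctuation removed, no stopword removal; deterministic
    order given the input order.
    """
    tokens: list[str] = []
    n_docs = 0
    for doc in docs:
        n_docs += 1
        tokens.extend(w2v_tokenize(doc.title))
        tokens.extend(w2v_tokenize(doc.description))
    if n_docs == 0 or not tokens:
        raise ValueError("cannot build a training corpus from an empty collection")
    return tokens


@dataclass
class EmbeddingModel:
    vocabulary: list[str]
    vectors: np.ndarray  # (V, d) float32
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.vocabulary) != len(set(self.vocabulary)):
            raise ValueError("vocabulary contains duplicates")
        if self.vectors.shape[0] != len(self.vocabulary):
            raise ValueError("one vector per vocabulary term required")
        self._index = {t: i for i, t in enumerate(self.vocabulary)}
        norms = np.linalg.norm(self.vectors, axis=1)
        norms[norms == 0.0] = 1.0
        self._unit = self.vectors / norms[:, None]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, term: str) -> bool:
        return term in self._index

    def vector(self, term: str) -> np.ndarray:
        return self.vectors[self._index[term]]

    def save(self, path: str | Path) -> None:
        """word2vec text format: header "V d", then one term + vector per line."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.vocabulary)} {self.dim}\n")
            for term, vec in zip(self.vocabulary, self.vectors):
                fh.write(term + " " + " ".join(f"{x:.6f}" for x in vec) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingModel":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            n, d = int(header[0]), int(header[1])
            vocab: list[str] = []
            vectors = np.empty((n, d), dtype=np.float32)
            for i in range(n):
                parts = fh.readline().rstrip("\n").split(" ")
                vocab.append(parts[0])
                vectors[i] = np.asarray(parts[1:1 + d], dtype=np.float32)
        return cls(vocab, vectors)


@njit(cache=True)
def _sgns_train(data, neg_cum, dim, window, negative, epochs, lr0, lr_min, seed,
                w_in, w_out):  # pragma: no cover - exercised via train_embeddings
    np.random.seed(seed)
    n = data.shape[0]
    total = float(epochs * n)
    step = 0
    grad = np.empty(dim, dtype=np.float32)
    for _ep in range(epochs):
        for i in range(n):
            lr = lr0 * (1.0 - step / total)
            if lr < lr_min:
                lr = lr_min
            step += 1
            w = data[i]
            b = np.random.randint(0, window)  # dynamic window shrink
            lo = i - window + b
            hi = i + window - b
            if lo < 0:
                lo = 0
            if hi >= n:
                hi = n - 1
            for j in range(lo, hi + 1):
                if j == i:
                    continue
                c = data[j]
                for k in range(dim):
                    grad[k] = 0.0
                # positive sample + `negative` draws from the noise dist
                for s in range(negative + 1):
                    if s == 0:
                        target = c
                        label = 1.0
                    else:
                        r = np.random.random()
                        target = np.searchsorted(neg_cum, r)
                        if target == w:
                            continue
                        label = 0.0
                    f = 0.0
                    for k in range(dim):
                        f += w_in[w, k] * w_out[target, k]
                    if f > 6.0:
                        sig = 1.0
                    elif f < -6.0:
                        sig = 0.0
                    else:
                        sig = 1.0 / (1.0 + np.exp(-f))
                    g = (label - sig) * lr
                    for k in range(dim):
                        grad[k] += g * w_out[target, k]
                        w_out[target, k] += g * w_in[w, k]
                for k in range(dim):
                    w_in[w, k] += grad[k]


def train_embeddings(corpus: Sequence[str], dim: int = 100, window: int = 5,
                     negative: int = 5, epochs: int = 5, seed: int = 1,
                     min_count: int = 1, lr: float = 0.025) -> EmbeddingModel:
    """Train SGNS vectors on a token stream; deterministic for a fixed seed."""
    if not corpus:
        raise ValueError("empty training corpus")
    counts: dict[str, int] = {}
    for tok in corpus:
        counts[tok] = counts.get(tok, 0) + 1
    vocab = sorted((t for t, c in counts.items() if c >= min_count),
                   key=lambda t: (-counts[t], t))
    if len(vocab) < 6:
        raise ValueError(f"vocabulary has {len(vocab)} terms; need at least 6 "
                         "to produce 5 expansion neighbors")
    index = {t: i for i, t in enumerate(vocab)}
    data = np.asarray([index[t] for t in corpus if t in index], dtype=np.int64)

    freq = np.asarray([counts[t] for t in vocab], dtype=np.float64) ** 0.75
    neg_cum = np.cumsum(freq / freq.sum())
    neg_cum[-1] = 1.0

    rng = np.random.default_rng(seed)
    w_in = ((rng.random((len(vocab), dim), dtype=np.float64) - 0.5) / dim
            ).astype(np.float32)
    w_out = np.zeros((len(vocab), dim), dtype=np.float32)

    _sgns_train(data, neg_cum, dim, window, negative, epochs,
                np.float32(lr), np.float32(lr * 1e-4), seed, w_in, w_out)
    if not np.all(np.isfinite(w_in)):
        raise RuntimeError("non-finite embedding values after training")
    meta = {"dim": dim, "window": window, "negative": negative,
            "epochs": epochs, "seed": seed, "min_count": min_count}
    return EmbeddingModel(vocab, w_in, meta)


def nearest(model: EmbeddingModel, term: str, n: int = 5) -> list[tuple[str, float]]:
    """The n highest-cosine in-vocabulary neighbors of ``term`` (self excluded)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if term not in model:
        logger.warning("term %r not in embedding vocabulary; no expansion", term)
        return []
    i = model._index[term]
    sims = model._unit @ model._unit[i]
    order = sorted((( -float(sims[j]), model.vocabulary[j]) for j in range(len(sims))
                    if j != i))
    return [(t, -neg) for neg, t in order[:n]]


@dataclass
class WeightedQuery:
    """Original query tokens plus down-weighted expansion tokens."""

    query_id: str
    original: list[str]
    expansions: list[str] = field(default_factory=list)
    w_orig: float = 0.9
    w_exp: float = 0.1
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.w_orig <= 1.0 and 0.0 < self.w_exp <= 1.0):
            raise ValueError("query weights must lie in (0, 1]")
        overlap = set(self.expansions) & set(self.original)
        if overlap:
            raise ValueError(f"expansion tokens collide with originals: {overlap}")
        if len(self.expansions) != len(set(self.expansions)):
            raise ValueError("expansion tokens must be deduplicated")


def expand_query(raw_query: RawQuery, entity_terms: Sequence[str],
                 model: EmbeddingModel | None, w_orig: float = 0.9,
                 w_exp: float = 0.1, n: int = 5,
                 stoplist: Stoplist | None = None) -> WeightedQuery:
    """Expand each entity word with its n nearest embedding neighbors.

    Multi-word entities contribute their individual words as seeds; seeds
    missing from the vocabulary contribute nothing; expansion terms already
    present in the original query are dropped.
    """
    if stoplist is None:
        stoplist = Stoplist.default(query_mode=True)
    original = preprocess(raw_query.text, stoplist)
    seeds: list[str] = []
    for entity in entity_terms:
        for word in w2v_tokenize(entity):
            if word not in seeds:
                seeds.append(word)
    expansions: list[str] = []
    provenance: dict[str, str] = {}
    if model is not None:
        original_set = set(original)
        for seed in seeds:
            for term, _cos in nearest(model, seed, n):
                if term in original_set or term in provenance:
                    continue
                expansions.append(term)
                provenance[term] = seed
    return WeightedQuery(query_id=raw_query.query_id, original=original,
                         expansions=expansions, w_orig=w_orig, w_exp=w_exp,
                         provenance=provenance)
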