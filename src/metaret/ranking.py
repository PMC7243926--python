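"""Document scoring: TFIDF, Dirichlet query likelihood, MRF and POS-MRF.

The dependence models score a document as

    r(Q, D) = sum_{c in {F, O, U}} theta_c * sum_{cliques} lambda * w * f(c, clique, D)

where f is a Dirichlet-smoothed log language-model probability, lambda is
the POS weight of the clique (mean of member term weights for pairs, and
identically 1 for the plain MRF), and w is the per-term query weight used
by expansion (original terms 0.9, expansion terms 0.1, otherwise 1).
Per-field scores over the title and description indexes are combined by a
weighted sum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

from metaret.corpus_io import RawQuery
from metaret.expansion import WeightedQuery
from metaret.indexer import FieldIndex, Stoplist, count_ordered, count_unordered, preprocess
from metaret.tagging import Tagger, pos_tag

logger = logging.getLogger(__name__)

MODELS = ("tfidf", "ql", "mrf", "posmrf")

#: POS-class weights: nouns, plural nouns, past-participle verbs, past-tense
#: verbs, adjectives, adverbs, singular proper nouns, everything else
DEFAULT_POS_WEIGHTS = {
    "NN": 0.5970,
    "NNS": 0.2265,
    "VBN": 0.3065,
    "VBD": 0.2260,
    "JJ": 0.3730,
    "RB": 0.1040,
    "NNP": 0.8930,
    "OTHER": 0.0,
}

POS_CLASSES = ("NN", "NNS", "VBN", "VBD", "JJ", "RB", "NNP", "OTHER")


@dataclass(frozen=True)
class PosWeights:
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_POS_WEIGHTS))

    def __post_init__(self) -> None:
        for cls in POS_CLASSES:
            if cls not in self.weights:
                raise ValueError(f"missing POS class {cls}")


def lambda_for(tag: str, pos_weights: PosWeights | None = None) -> float:
    """Weight for a Penn tag: exact class match, everything else -> OTHER."""
    weights = (pos_weights or PosWeights()).weights
    return weights.get(tag, weights["OTHER"]) if tag in weights else weights["OTHER"]


@dataclass(frozen=True)
class CliqueConfig:
    theta_F: float = 0.8
    theta_O: float = 0.1
    theta_U: float = 0.1
    dirichlet_mu: float = 2500.0
    ordered_window: int = 1
    unordered_window: int = 8
    field_weights: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if min(self.theta_F, self.theta_O, self.theta_U) < 0:
            raise ValueError("theta weights must be >= 0")
        if self.dirichlet_mu <= 0:
            raise ValueError("dirichlet_mu must be > 0")


@dataclass(frozen=True)
class QueryTerm:
    token: str
    tag: str = "NN"
    weight: float = 1.0
    is_expansion: bool = False


@dataclass
class TaggedQuery:
    query_id: str
    terms: list[QueryTerm]

    @property
    def originals(self) -> list[QueryTerm]:
        return [t for t in self.terms if not t.is_expansion]

    @property
    def expansions(self) -> list[QueryTerm]:
        return [t for t in self.terms if t.is_expansion]


@dataclass
class RankedList:
    query_id: str
    items: list[tuple[str, float]] = field(default_factory=list)

    def doc_ids(self) -> list[str]:
        return [d for d, _s in self.items]

    def __len__(self) -> int:
        return len(self.items)


def tag_query(query: RawQuery | str, stoplist: Stoplist | None = None,
              weighted: WeightedQuery | None = None,
              tagger: Tagger | None = None, query_id: str = "") -> TaggedQuery:
    """Build a TaggedQuery from raw text or an expansion-weighted query."""
    if weighted is not None:
        originals = list(weighted.original)
        w_orig, w_exp = weighted.w_orig, weighted.w_exp
        expansions = list(weighted.expansions)
    else:
        if isinstance(query, RawQuery):
            query_id = query.query_id
            text = query.text
        else:
            text = query
        if stoplist is None:
            stoplist = Stoplist.default(query_mode=True)
        originals = preprocess(text, stoplist)
        w_orig, expansions, w_exp = 1.0, [], 0.1
    if isinstance(query, RawQuery):
        query_id = query.query_id
    terms: list[QueryTerm] = []
    if originals:
        for token, tag in zip(originals, pos_tag(originals, tagger)):
            terms.append(QueryTerm(token, tag, w_orig, False))
    if expansions:
        for token, tag in zip(expansions, pos_tag(expansions, tagger)):
            terms.append(QueryTerm(token, tag, w_exp, True))
    return TaggedQuery(query_id=query_id, terms=terms)


# --- potentials --------------------------------------------------------------

def _collection_prob(collection_tf: int, collection_length: int) -> float:
    if collection_length <= 0:
        raise ValueError("empty collection")
    if collection_tf > 0:
        return collection_tf / collection_length
    # out-of-collection floor: keeps potentials finite, preserves ordering
    return 1.0 / (collection_length + 1)


def potential_F(term: str, doc_id: str, index: FieldIndex, mu: float) -> float:
    """log of the Dirichlet-smoothed unigram probability of ``term`` in ``doc_id``."""
    p_c = _collection_prob(index.collection_tf(term), index.collection_length)
    tf = index.tf(term, doc_id)
    dl = index.doc_length.get(doc_id, 0)
    return math.log((tf + mu * p_c) / (dl + mu))


def pair_doc_count(t1: str, t2: str, doc_id: str, index: FieldIndex,
                   kind: str, window: int) -> int:
    p1 = index.positions(t1, doc_id)
    p2 = index.positions(t2, doc_id)
    if not p1 or not p2:
        return 0
    counter = count_ordered if kind == "O" else count_unordered
    return counter(p1, p2, window)


def pair_collection_count(t1: str, t2: str, index: FieldIndex,
                          kind: str, window: int) -> int:
    docs1 = index.postings.get(t1, {})
    docs2 = index.postings.get(t2, {})
    small, other = (docs1, docs2) if len(docs1) <= len(docs2) else (docs2, docs1)
    return sum(pair_doc_count(t1, t2, d, index, kind, window)
               for d in small if d in other)


def _potential_pair(t1: str, t2: str, doc_id: str, index: FieldIndex,
                    config: CliqueConfig, kind: str,
                    collection_count: int | None = None) -> float:
    window = config.ordered_window if kind == "O" else config.unordered_window
    if collection_count is None:
        collection_count = pair_collection_count(t1, t2, index, kind, window)
    p_c = _collection_prob(collection_count, index.collection_length)
    n = pair_doc_count(t1, t2, doc_id, index, kind, window)
    dl = index.doc_length.get(doc_id, 0)
    mu = config.dirichlet_mu
    return math.log((n + mu * p_c) / (dl + mu))


def potential_O(pair: tuple[str, str], doc_id: str, index: FieldIndex,
                config: CliqueConfig) -> float:
    """Dirichlet-smoothed log probability of the ordered-window pseudo-term."""
    return _potential_pair(pair[0], pair[1], doc_id, index, config, "O")


def potential_U(pair: tuple[str, str], doc_id: str, index: FieldIndex,
                config: CliqueConfig) -> float:
    """Dirichlet-smoothed log probability of the unordered-window pseudo-term."""
    return _potential_pair(pair[0], pair[1], doc_id, index, config, "U")


# --- scorer ------------------------------------------------------------------

class Scorer:
    """Scores documents for one (index pair, config); caches pair statistics."""

    def __init__(self, title_index: FieldIndex, desc_index: FieldIndex,
                 config: CliqueConfig | None = None,
                 pos_weights: PosWeights | None = None) -> None:
        self.indices = (title_index, desc_index)
        self.config = config or CliqueConfig()
        self.pos_weights = pos_weights or PosWeights()
        self._pair_cache: dict[tuple, int] = {}
        self._norm_cache: dict[int, dict[str, float]] = {}

    # -- dependence-model scoring --------------------------------------------
    def _pair_stat(self, t1: str, t2: str, fi: int, kind: str) -> int:
        key = (t1, t2, fi, kind)
        if key not in self._pair_cache:
            window = (self.config.ordered_window if kind == "O"
                      else self.config.unordered_window)
            self._pair_cache[key] = pair_collection_count(
                t1, t2, self.indices[fi], kind, window)
        return self._pair_cache[key]

    def _field_dependence_score(self, query: TaggedQuery, doc_id: str, fi: int,
                                use_pos: bool) -> float:
        cfg = self.config
        index = self.indices[fi]
        lam = (lambda t: lambda_for(t, self.pos_weights)) if use_pos else (lambda t: 1.0)
        score = 0.0
        # F cliques: every query term, originals and expansion terms alike
        if cfg.theta_F != 0.0:
            part = 0.0
            for term in query.terms:
                part += lam(term.tag) * term.weight * potential_F(
                    term.token, doc_id, index, cfg.dirichlet_mu)
            score += cfg.theta_F * part
        originals = query.originals
        # O cliques: adjacent original-term pairs
        if cfg.theta_O != 0.0 and len(originals) > 1:
            part = 0.0
            for a, b in zip(originals, originals[1:]):
                cc = self._pair_stat(a.token, b.token, fi, "O")
                f = _potential_pair(a.token, b.token, doc_id, index, cfg, "O", cc)
                part += (0.5 * (lam(a.tag) + lam(b.tag))
                         * 0.5 * (a.weight + b.weight) * f)
            score += cfg.theta_O * part
        # U cliques: all unordered original-term pairs
        if cfg.theta_U != 0.0 and len(originals) > 1:
            part = 0.0
            for i in range(len(originals)):
                for j in range(i + 1, len(originals)):
                    a, b = originals[i], originals[j]
                    cc = self._pair_stat(a.token, b.token, fi, "U")
                    f = _potential_pair(a.token, b.token, doc_id, index, cfg, "U", cc)
                    part += (0.5 * (lam(a.tag) + lam(b.tag))
                             * 0.5 * (a.weight + b.weight) * f)
            score += cfg.theta_U * part
        return score

    def score_posmrf(self, query: TaggedQuery, doc_id: str) -> float:
        return self._combine(query, doc_id, use_pos=True, config=self.config)

    def score_mrf(self, query: TaggedQuery, doc_id: str) -> float:
        return self._combine(query, doc_id, use_pos=False, config=self.config)

    def score_ql(self, query: TaggedQuery, doc_id: str) -> float:
        cfg = CliqueConfig(theta_F=1.0, theta_O=0.0, theta_U=0.0,
                           dirichlet_mu=self.config.dirichlet_mu,
                           ordered_window=self.config.ordered_window,
                           unordered_window=self.config.unordered_window,
                           field_weights=self.config.field_weights)
        return self._combine(query, doc_id, use_pos=False, config=cfg)

    def _combine(self, query: TaggedQuery, doc_id: str, use_pos: bool,
                 config: CliqueConfig) -> float:
        if not query.terms:
            logger.warning("query %s empty after preprocessing; score 0", query.query_id)
            return 0.0
        saved = self.config
        self.config = config
        try:
            total = 0.0
            for fi, fw in enumerate(config.field_weights):
                # a field that is empty across the whole collection carries
                # no evidence and is skipped
                if fw != 0.0 and self.indices[fi].collection_length > 0:
                    total += fw * self._field_dependence_score(query, doc_id, fi, use_pos)
            return total
        finally:
            self.config = saved

    # -- tfidf ----------------------------------------------------------------
    def _doc_norms(self, fi: int) -> dict[str, float]:
        if fi not in self._norm_cache:
            index = self.indices[fi]
            n_docs = index.doc_count
            acc: dict[str, float] = {d: 0.0 for d in index.doc_length}
            for term, per_doc in index.postings.items():
                df = len(per_doc)
                idf = math.log(n_docs / df) if df else 0.0
                if idf == 0.0:
                    continue
                for doc_id, positions in per_doc.items():
                    w = (1.0 + math.log(len(positions))) * idf
                    acc[doc_id] += w * w
            self._norm_cache[fi] = {d: math.sqrt(v) for d, v in acc.items()}
        return self._norm_cache[fi]

    def score_tfidf(self, query: TaggedQuery, doc_id: str) -> float:
        if not query.terms:
            return 0.0
        total = 0.0
        for fi, fw in enumerate(self.config.field_weights):
            if fw == 0.0:
                continue
            index = self.indices[fi]
            n_docs = index.doc_count
            qtf: dict[str, float] = {}
            for term in query.terms:
                qtf[term.token] = qtf.get(term.token, 0.0) + term.weight
            dot = 0.0
            q_norm_sq = 0.0
            for token, wq_tf in qtf.items():
                df = index.df(token)
                if df == 0:
                    continue
                idf = math.log(n_docs / df)
                if idf == 0.0:
                    continue
                wq = (1.0 + math.log(wq_tf)) * idf if wq_tf > 0 else 0.0
                q_norm_sq += wq * wq
                tf = index.tf(token, doc_id)
                if tf:
                    dot += wq * (1.0 + math.log(tf)) * idf
            d_norm = self._doc_norms(fi).get(doc_id, 0.0)
            if dot and d_norm and q_norm_sq:
                total += fw * dot / (math.sqrt(q_norm_sq) * d_norm)
        return total

    # -- retrieval ------------------------------------------------------------
    def score(self, query: TaggedQuery, doc_id: str, model: str) -> float:
        if model == "tfidf":
            return self.score_tfidf(query, doc_id)
        if model == "ql":
            return self.score_ql(query, doc_id)
        if model == "mrf":
            return self.score_mrf(query, doc_id)
        if model == "posmrf":
            return self.score_posmrf(query, doc_id)
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")

    def candidates(self, query: TaggedQuery) -> set[str]:
        docs: set[str] = set()
        for term in query.terms:
            for index in self.indices:
                docs.update(index.docs_with(term.token))
        return docs

    def retrieve(self, query: TaggedQuery, model: str = "posmrf",
                 k: int = 10000) -> RankedList:
        """Top-k documents matching at least one query term, ties by doc_id."""
        if k < 1:
            raise ValueError("k must be >= 1")
        if model not in MODELS:
            raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
        if not query.terms:
            logger.warning("query %s is empty; returning no results", query.query_id)
            return RankedList(query.query_id, [])
        scored = [(doc_id, self.score(query, doc_id, model))
                  for doc_id in self.candidates(query)]
        scored.sort(key=lambda p: (-p[1], p[0]))
        return RankedList(query.query_id, scored[:k])


# --- module-level convenience wrappers --------------------------------------

def score_posmrf(query: TaggedQuery, doc_id: str,
                 indices: tuple[FieldIndex, FieldIndex],
                 config: CliqueConfig | None = None,
                 pos_weights: PosWeights | None = None) -> float:
    return Scorer(*indices, config=config, pos_weights=pos_weights).score_posmrf(query, doc_id)


def score_mrf(query: TaggedQuery, doc_id: str,
              indices: tuple[FieldIndex, FieldIndex],
              config: CliqueConfig | None = None) -> float:
    return Scorer(*indices, config=config).score_mrf(query, doc_id)


def score_tfidf(query: TaggedQuery, doc_id: str,
                indices: tuple[FieldIndex, FieldIndex],
                field_weights: tuple[float, float] = (0.5, 0.5)) -> float:
    cfg = CliqueConfig(field_weights=field_weights)
    return Scorer(*indices, config=cfg).score_tfidf(query, doc_id)


def retrieve(query: TaggedQuery, indices: tuple[FieldIndex, FieldIndex],
             model: str = "posmrf", k: int = 10000,
             config: CliqueConfig | None = None,
             pos_weights: PosWeights | None = None) -> RankedList:
    return Scorer(*indices, config=config, pos_weights=pos_weights).retrieve(query, model, k)
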