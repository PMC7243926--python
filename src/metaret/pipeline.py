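"""End-to-end system configurations: model x {+/-expansion} x {+/-rerank}.

A :class:`Benchmark` loads a corpus directory (documents, queries, optional
qrels, entity dictionary), builds the two-field index, trains or loads the
expansion embeddings, extracts entities for every document and query, and
runs any of the twelve standard system configurations to a TREC run file.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from metaret import corpus_io
from metaret.corpus_io import RawQuery, SampledQrels
from metaret.entities import EntityDictionary, extract_entities, shared_entity_count
from metaret.expansion import (EmbeddingModel, WeightedQuery,
                               build_training_corpus, expand_query,
                               train_embeddings)
from metaret.indexer import Stoplist, build_index, preprocess
from metaret.metrics import EvalResult, evaluate
from metaret.ranking import CliqueConfig, PosWeights, RankedList, Scorer, tag_query
from metaret.rerank import RerankInput, rerank

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SystemConfig:
    model: str = "posmrf"            # tfidf | mrf | posmrf
    use_expansion: bool = False
    use_rerank: bool = False
    clique: CliqueConfig = field(default_factory=CliqueConfig)
    pos_weights: PosWeights = field(default_factory=PosWeights)
    k_retrieve: int = 10000
    k_final: int = 1000
    w_orig: float = 0.9
    w_exp: float = 0.1
    n_expansion: int = 5
    tag: str = ""

    def __post_init__(self) -> None:
        if self.model not in ("tfidf", "mrf", "posmrf"):
            raise ValueError(f"unknown system model {self.model!r}")
        if not self.tag:
            object.__setattr__(self, "tag", self.default_tag())

    def default_tag(self) -> str:
        tag = self.model
        if self.use_expansion:
            tag += "+we"
        if self.use_rerank:
            tag += "+rr"
        return tag


def all_system_configs(**overrides) -> list[SystemConfig]:
    """The twelve standard configurations (3 models x +/-WE x +/-RR)."""
    configs = []
    for model in ("tfidf", "mrf", "posmrf"):
        for use_expansion in (False, True):
            for use_rerank in (False, True):
                configs.append(SystemConfig(model=model,
                                            use_expansion=use_expansion,
                                            use_rerank=use_rerank,
                                            **overrides))
    return configs


class Benchmark:
    """All shared per-corpus state needed to run system configurations."""

    def __init__(self, docs, queries, dictionary: EntityDictionary | None = None,
                 qrels: SampledQrels | None = None,
                 embeddings: EmbeddingModel | None = None,
                 doc_annotations=None, query_annotations=None,
                 stoplist: Stoplist | None = None,
                 query_stoplist: Stoplist | None = None) -> None:
        self.docs = list(docs)
        self.queries = list(queries)
        self.dictionary = dictionary or EntityDictionary()
        self.qrels = qrels
        self.stoplist = stoplist or Stoplist.default()
        self.query_stoplist = query_stoplist or Stoplist.default(query_mode=True)
        self.doc_annotations = doc_annotations or {}
        self.query_annotations = query_annotations or {}
        self._embeddings = embeddings
        self._indices = None
        self._doc_entity_ids: dict[str, set[str]] | None = None
        self._query_mentions: dict[str, list] | None = None

    # ---- corpus-directory constructor --------------------------------------
    @classmethod
    def from_dir(cls, corpus_dir: str | Path, **kwargs) -> "Benchmark":
        corpus_dir = Path(corpus_dir)
        docs, _ = corpus_io.load_datasets(corpus_dir / "docs.jsonl")
        queries = corpus_io.read_queries(corpus_dir / "queries.tsv")
        dict_path = corpus_dir / "dictionary.tsv"
        dictionary = corpus_io.read_dictionary(dict_path) if dict_path.exists() else None
        qrels_path = corpus_dir / "qrels.txt"
        qrels = (corpus_io.read_qrels(qrels_path, stratified=True)
                 if qrels_path.exists() else None)
        annotations = {}
        for source in ("pubtator", "becas"):
            ann_path = corpus_dir / f"annotations.{source}.tsv"
            if ann_path.exists():
                for unit, ms in corpus_io.read_annotations(ann_path).items():
                    annotations.setdefault(unit, {}).setdefault(source, []).extend(ms)
        return cls(docs, queries, dictionary=dictionary, qrels=qrels,
                   doc_annotations=annotations, **kwargs)

    # ---- lazily built artifacts --------------------------------------------
    @property
    def indices(self):
        if self._indices is None:
            t0 = time.perf_counter()
            self._indices = build_index(self.docs, self.stoplist)
            logger.info("indexed %d docs in %.1fs", len(self.docs),
                        time.perf_counter() - t0)
        return self._indices

    def train_expansion_model(self, seed: int = 1, **params) -> EmbeddingModel:
        t0 = time.perf_counter()
        corpus = build_training_corpus(self.docs)
        self._embeddings = train_embeddings(corpus, seed=seed, **params)
        logger.info("trained embeddings (%d tokens) in %.1fs", len(corpus),
                    time.perf_counter() - t0)
        return self._embeddings

    @property
    def embeddings(self) -> EmbeddingModel | None:
        return self._embeddings

    def _annotations_for(self, unit_id: str):
        return self.doc_annotations.get(unit_id) or None

    @property
    def doc_entity_ids(self) -> dict[str, set[str]]:
        if self._doc_entity_ids is None:
            t0 = time.perf_counter()
            out: dict[str, set[str]] = {}
            for doc in self.docs:
                mentions = []
                for text in (doc.title, doc.description):
                    mentions.extend(extract_entities(
                        text, self.dictionary, unit_id=doc.doc_id,
                        annotations=self._annotations_for(doc.doc_id)))
                out[doc.doc_id] = {m.entity_id for m in mentions}
            self._doc_entity_ids = out
            logger.info("extracted entities for %d docs in %.1fs",
                        len(self.docs), time.perf_counter() - t0)
        return self._doc_entity_ids

    @property
    def query_mentions(self) -> dict[str, list]:
        if self._query_mentions is None:
            self._query_mentions = {
                q.query_id: extract_entities(
                    q.text, self.dictionary, unit_id=q.query_id,
                    annotations=self.query_annotations.get(q.query_id) or None)
                for q in self.queries
            }
        return self._query_mentions

    # ---- running one configuration -----------------------------------------
    def weighted_query(self, query: RawQuery, config: SystemConfig) -> WeightedQuery:
        if not config.use_expansion:
            return WeightedQuery(
                query_id=query.query_id,
                original=preprocess(query.text, self.query_stoplist),
                w_orig=1.0, w_exp=config.w_exp)
        if self.embeddings is None:
            raise RuntimeError(
                "configuration requests query expansion but no embedding model "
                "is available; call train_expansion_model() or pass embeddings=")
        entity_terms = [m.surface for m in self.query_mentions[query.query_id]]
        return expand_query(query, entity_terms, self.embeddings,
                            w_orig=config.w_orig, w_exp=config.w_exp,
                            n=config.n_expansion, stoplist=self.query_stoplist)

    def run_system(self, config: SystemConfig) -> dict[str, RankedList]:
        scorer = Scorer(*self.indices, config=config.clique,
                        pos_weights=config.pos_weights)
        results: dict[str, RankedList] = {}
        for query in self.queries:
            t0 = time.perf_counter()
            wq = self.weighted_query(query, config)
            tq = tag_query(query, weighted=wq)
            ranked = scorer.retrieve(tq, model=config.model, k=config.k_retrieve)
            if config.use_rerank and ranked.items:
                q_ids = {m.entity_id for m in self.query_mentions[query.query_id]}
                overlap = {doc_id: len(q_ids & self.doc_entity_ids.get(doc_id, set()))
                           for doc_id, _s in ranked.items}
                ranked = rerank(RerankInput(ranked, overlap), config.k_final)
            else:
                ranked = RankedList(ranked.query_id, ranked.items[:config.k_final])
            results[query.query_id] = ranked
            logger.info("%s query %s: %d docs in %.2fs", config.tag,
                        query.query_id, len(ranked), time.perf_counter() - t0)
        return results

    def run_to_file(self, config: SystemConfig, out_dir: str | Path,
                    ) -> tuple[Path, EvalResult | None]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        results = self.run_system(config)
        run_path = out_dir / f"{config.tag}.run"
        corpus_io.write_run(results, config.tag, run_path,
                            max_per_query=config.k_final)
        eval_result = None
        if self.qrels is not None:
            rankings = {qid: rl.doc_ids() for qid, rl in results.items()}
            eval_result = evaluate(rankings, self.qrels)
            (out_dir / f"{config.tag}.eval.tsv").write_text(
                eval_result.to_tsv(), encoding="utf-8")
        return run_path, eval_result

    def run_all(self, out_dir: str | Path, embed_seed: int = 1,
                **overrides) -> dict[str, tuple[Path, EvalResult | None]]:
        """Run all twelve configurations, training embeddings once if needed."""
        configs = all_system_configs(**overrides)
        if any(c.use_expansion for c in configs) and self.embeddings is None:
            self.train_expansion_model(seed=embed_seed)
        out = {}
        for config in configs:
            out[config.tag] = self.run_to_file(config, out_dir)
        return out
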