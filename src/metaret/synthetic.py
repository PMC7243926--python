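"""Synthetic test collections with planted retrieval structure.

Documents mix Zipf-distributed background and topic vocabularies.  Each
synonym family has two interchangeable members that never co-occur in one
document but share distinctive collocate contexts, so embedding training
can recover the synonymy.  Relevance is planted per query: grade-2
documents contain the full required entity combination co-occurring,
grade-1 documents contain a strict subset scattered without co-mention.
The family members double as entity surfaces normalized to one identifier,
which makes entity-overlap re-ranking exercise the same structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from metaret.corpus_io import (DatasetDoc, RawQuery, SampledQrels,
                               write_datasets, write_dictionary, write_qrels,
                               write_queries)


@dataclass
class SynthConfig:
    n_docs: int = 5000
    n_topics: int = 5
    background_vocab: int = 300
    topic_vocab: int = 150
    n_synonym_families: int = 10
    doc_len_mean: int = 80
    title_len: int = 6
    n_queries: int = 10
    grade2_per_query: int = 15
    grade1_per_query: int = 10
    judged_nonrel_per_query: int = 30
    family_doc_rate: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_docs", "n_topics", "background_vocab", "topic_vocab",
                     "n_synonym_families", "doc_len_mean", "n_queries",
                     "grade2_per_query", "grade1_per_query"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        per_topic = self.n_docs // self.n_topics
        need = (self.grade2_per_query + self.grade1_per_query
                + self.judged_nonrel_per_query)
        queries_per_topic = -(-self.n_queries // self.n_topics)
        if need * queries_per_topic > per_topic:
            raise ValueError("not enough documents per topic for the relevance plan")


@dataclass
class SynonymFamily:
    member_a: str
    member_b: str
    topic: int
    collocates: list[str]
    entity_id: str


@dataclass
class SynthCollection:
    docs: list[DatasetDoc]
    dictionary_rows: list[tuple[str, str, str, str]]
    queries: list[RawQuery]
    qrels: SampledQrels
    truth: dict = field(default_factory=dict)


def _zipf_probs(n: int) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


def generate(config: SynthConfig) -> SynthCollection:
    """Generate a full collection; byte-identical for a fixed config."""
    rng = np.random.default_rng(config.seed)
    background = [f"w{i}" for i in range(config.background_vocab)]
    topics = [[f"t{t}w{i}" for i in range(config.topic_vocab)]
              for t in range(config.n_topics)]
    bg_p = _zipf_probs(config.background_vocab)
    topic_p = _zipf_probs(config.topic_vocab)

    # context profiles: per family a fixed subset of its topic vocabulary,
    # disjoint between families of the same topic, used to build snippet
    # contexts -- shared but non-exclusive contexts make the two members
    # paradigmatic nearest neighbors without creating collocate distractors
    profile_size = min(15, config.topic_vocab // 4)
    # start profiles past the Zipf head so profile words are mid-frequency
    profile_cursor = {t: min(20, config.topic_vocab // 5)
                      for t in range(config.n_topics)}
    families = []
    for f in range(config.n_synonym_families):
        topic = f % config.n_topics
        start = profile_cursor[topic]
        profile = topics[topic][start:start + profile_size]
        profile_cursor[topic] = start + profile_size
        if len(profile) < profile_size:
            raise ValueError("topic vocabulary too small for family profiles")
        families.append(SynonymFamily(
            member_a=f"syna{f}", member_b=f"synb{f}", topic=topic,
            collocates=profile, entity_id=f"mesh:d{f}"))
    fams_by_topic: dict[int, list[SynonymFamily]] = {}
    for fam in families:
        fams_by_topic.setdefault(fam.topic, []).append(fam)

    # ---- relevance plan ----------------------------------------------------
    queries: list[RawQuery] = []
    plan: dict[str, dict] = {}
    per_topic_docs: dict[int, list[int]] = {
        t: [] for t in range(config.n_topics)}
    doc_topic = rng.integers(0, config.n_topics, size=config.n_docs)
    for i, t in enumerate(doc_topic):
        per_topic_docs[int(t)].append(i)
    cursor = {t: 0 for t in range(config.n_topics)}

    def take(topic: int, count: int) -> list[int]:
        got = per_topic_docs[topic][cursor[topic]:cursor[topic] + count]
        cursor[topic] += count
        if len(got) < count:
            raise ValueError("not enough documents in topic for the relevance plan")
        return got

    for q in range(config.n_queries):
        fam = families[q % config.n_synonym_families]
        topic = fam.topic
        qid = f"q{q}"
        gene = f"gene{q}"
        g2 = take(topic, config.grade2_per_query)
        g1 = take(topic, config.grade1_per_query)
        g0 = take(topic, config.judged_nonrel_per_query)
        n_a = max(1, int(round(0.4 * len(g2))))
        queries.append(RawQuery(
            qid, f"Find data on {fam.member_a} and {gene} across all databases"))
        plan[qid] = {
            "topic": topic, "family": families.index(fam), "gene": gene,
            "required": [f"entrez:{gene}", fam.entity_id],
            "grade2": g2, "grade1": g1, "grade0": g0,
            "a_phrased": g2[:n_a], "b_phrased": g2[n_a:],
        }

    # roles per doc index
    role: dict[int, tuple[str, str]] = {}   # doc index -> (qid, grade role)
    for qid, p in plan.items():
        for i in p["grade2"]:
            role[i] = (qid, "g2")
        for i in p["grade1"]:
            role[i] = (qid, "g1")
        for i in p["grade0"]:
            role[i] = (qid, "g0")

    # ---- document generation ----------------------------------------------
    docs: list[DatasetDoc] = []
    doc_entities: dict[str, list[str]] = {}
    for i in range(config.n_docs):
        topic = int(doc_topic[i])
        doc_id = f"d{i:05d}"
        length = max(20, int(rng.poisson(config.doc_len_mean)))
        n_bg = int(round(0.3 * length))
        body = list(rng.choice(background, size=n_bg, p=bg_p))
        body += list(rng.choice(topics[topic], size=length - n_bg, p=topic_p))
        rng.shuffle(body)

        qid, r = role.get(i, (None, None))
        fam_members: dict[int, str] = {}
        for fam in fams_by_topic.get(topic, []):
            f_idx = families.index(fam)
            if qid is not None and plan[qid]["family"] == f_idx:
                continue  # the planted family is controlled by the role below
            if rng.random() < config.family_doc_rate:
                member = fam.member_a if rng.random() < 0.5 else fam.member_b
                fam_members[f_idx] = member

        entities: list[str] = []
        if r == "g2":
            p = plan[qid]
            fam = families[p["family"]]
            member = fam.member_a if i in p["a_phrased"] else fam.member_b
            fam_members[p["family"]] = member
            # required entities co-occur: adjacent snippets, twice
            for _rep in range(2):
                pos = int(rng.integers(0, len(body)))
                body[pos:pos] = [p["gene"], member]
            entities.extend([f"entrez:{p['gene']}", fam.entity_id])
        elif r == "g1":
            p = plan[qid]
            # strict subset: the gene only, scattered without co-mention
            third = max(1, len(body) // 3)
            body.insert(int(rng.integers(0, third)), p["gene"])
            body.insert(int(rng.integers(2 * third, len(body))), p["gene"])
            entities.append(f"entrez:{p['gene']}")

        # family collocate snippets (3 per present member)
        for f_idx, member in fam_members.items():
            fam = families[f_idx]
            for _rep in range(3):
                c1, c2 = rng.choice(fam.collocates, size=2, replace=False)
                pos = int(rng.integers(0, len(body)))
                body[pos:pos] = [str(c1), member, str(c2)]
            if fam.entity_id not in entities:
                entities.append(fam.entity_id)

        title_tokens = list(rng.choice(topics[topic], size=config.title_len,
                                       p=topic_p))
        docs.append(DatasetDoc(doc_id, " ".join(title_tokens), " ".join(body)))
        doc_entities[doc_id] = entities

    # ---- dictionary, qrels, truth ------------------------------------------
    dictionary_rows: list[tuple[str, str, str, str]] = []
    for q in range(config.n_queries):
        gene = f"gene{q}"
        dictionary_rows.append((gene, f"entrez:{gene}", "GENE", "entrez"))
    for fam in families:
        dictionary_rows.append((fam.member_a, fam.entity_id, "DISO", "mesh"))
        dictionary_rows.append((fam.member_b, fam.entity_id, "DISO", "mesh"))

    judgments: dict[tuple[str, str], int] = {}
    strata: dict[tuple[str, str], str] = {}
    for qid, p in plan.items():
        for i in p["grade2"]:
            judgments[(qid, f"d{i:05d}")] = 2
        for i in p["grade1"]:
            judgments[(qid, f"d{i:05d}")] = 1
        for i in p["grade0"]:
            judgments[(qid, f"d{i:05d}")] = 0
    for pair in judgments:
        strata[pair] = "all"
    counts: dict[tuple[str, str], int] = {}
    for (qid, _d) in judgments:
        counts[(qid, "all")] = counts.get((qid, "all"), 0) + 1
    qrels = SampledQrels(judgments=judgments, strata=strata,
                         stratum_meta={k: (n, n) for k, n in counts.items()})

    truth = {
        "families": [{"a": fam.member_a, "b": fam.member_b, "topic": fam.topic,
                      "entity_id": fam.entity_id, "collocates": fam.collocates}
                     for fam in families],
        "per_query": {qid: {k: ([f"d{i:05d}" for i in v]
                               if k in ("grade2", "grade1", "grade0",
                                        "a_phrased", "b_phrased") else v)
                            for k, v in p.items()}
                      for qid, p in plan.items()},
        "doc_entities": doc_entities,
    }
    return SynthCollection(docs=docs, dictionary_rows=dictionary_rows,
                           queries=queries, qrels=qrels, truth=truth)


def write_collection(coll: SynthCollection, out_dir: str | Path) -> dict[str, Path]:
    """Write a collection in exactly the formats corpus_io reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "docs": out / "docs.jsonl",
        "queries": out / "queries.tsv",
        "qrels": out / "qrels.txt",
        "dictionary": out / "dictionary.tsv",
        "truth": out / "truth.json",
    }
    write_datasets(coll.docs, paths["docs"])
    write_queries(coll.queries, paths["queries"])
    write_qrels(coll.qrels, paths["qrels"])
    write_dictionary(coll.dictionary_rows, paths["dictionary"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(coll.truth, fh, indent=1, sort_keys=True)
    return paths


def sample_qrels(qrels: SampledQrels, rate: float, seed: int) -> SampledQrels:
    """Uniform per-stratum sample of judged pairs with recorded pool sizes."""
    if not 0.0 < rate <= 1.0:
        raise ValueError("rate must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    by_stratum: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for pair in sorted(qrels.judgments):
        qid = pair[0]
        stratum = qrels.stratum_of(*pair)
        by_stratum.setdefault((qid, stratum), []).append(pair)
    judgments: dict[tuple[str, str], int] = {}
    strata: dict[tuple[str, str], str] = {}
    meta: dict[tuple[str, str], tuple[int, int]] = {}
    for key, pairs in sorted(by_stratum.items()):
        pool = len(pairs)
        n_sample = int(rate * pool)
        if n_sample == 0 and pool > 0:
            import logging
            logging.getLogger(__name__).warning(
                "stratum %s: sampling rate %.3f yields an empty sample", key, rate)
        chosen = rng.choice(pool, size=n_sample, replace=False) if n_sample else []
        for idx in sorted(int(c) for c in chosen):
            pair = pairs[idx]
            judgments[pair] = qrels.judgments[pair]
            strata[pair] = key[1]
        meta[key] = (pool, n_sample)
    return SampledQrels(judgments=judgments, strata=strata, stratum_meta=meta)
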