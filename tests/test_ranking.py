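import math

import numpy as np
import pytest

from conftest import random_corpus, random_query
from metaret.corpus_io import DatasetDoc, RawQuery
from metaret.indexer import Stoplist, build_index, count_ordered, count_unordered
from metaret.ranking import (DEFAULT_POS_WEIGHTS, CliqueConfig, PosWeights,
                             QueryTerm, Scorer, TaggedQuery, lambda_for,
                             pair_collection_count, potential_F, potential_O,
                             potential_U, tag_query)

UNIFORM_POS = PosWeights({c: 1.0 for c in DEFAULT_POS_WEIGHTS})


def make_query(tokens, tags=None, weights=None, expansion=None):
    tags = tags or ["NN"] * len(tokens)
    weights = weights or [1.0] * len(tokens)
    terms = [QueryTerm(t, g, w) for t, g, w in zip(tokens, tags, weights)]
    for token in expansion or []:
        terms.append(QueryTerm(token, "NN", 0.1, True))
    return TaggedQuery("q", terms)


class TestLambdaFor:
    @pytest.mark.parametrize("tag,value", [
        ("NN", 0.5970), ("NNS", 0.2265), ("VBN", 0.3065), ("VBD", 0.2260),
        ("JJ", 0.3730), ("RB", 0.1040), ("NNP", 0.8930),
    ])
    def test_exact_classes(self, tag, value):
        assert lambda_for(tag) == value

    @pytest.mark.parametrize("tag", ["CD", "IN", "DT", "VB", "VBG", "NNPS", ""])
    def test_everything_else_is_other(self, tag):
        assert lambda_for(tag) == 0.0


class TestPotentialF:
    def test_hand_computed(self):
        # tf=2, |D|=10, mu=10, P(term|C)=0.01 -> log(2.1/20)
        docs = [DatasetDoc("d1", "x " * 8 + "t t", "")]
        # collection stats: want P(t|C)=0.01 -> pad collection with more docs
        filler = [DatasetDoc(f"f{i}", "x " * 19, "") for i in range(10)]
        title, _ = build_index(docs + filler, Stoplist.empty())
        assert title.collection_length == 200
        assert title.collection_tf("t") == 2
        assert math.isclose(potential_F("t", "d1", title, mu=10.0),
                            math.log(0.105), rel_tol=1e-12)

    def test_monotone_in_tf(self, tiny_indices):
        title, _ = tiny_indices
        with_term = potential_F("gene", "d1", title, 100.0)
        without = potential_F("gene", "d2", title, 100.0)
        # d2 is shorter, so compare against a same-length hypothetical via
        # the formula directly: tf=0 on d1's length
        dl = title.doc_length["d1"]
        p_c = title.collection_tf("gene") / title.collection_length
        zero_tf = math.log((0 + 100.0 * p_c) / (dl + 100.0))
        assert with_term > zero_tf
        assert without < with_term

    def test_mu_infinity_limit(self, tiny_indices):
        title, _ = tiny_indices
        p_c = title.collection_tf("disease") / title.collection_length
        val = potential_F("disease", "d1", title, mu=1e12)
        assert math.isclose(val, math.log(p_c), rel_tol=1e-6)

    def test_out_of_collection_floor_is_finite(self, tiny_indices):
        title, _ = tiny_indices
        val = potential_F("zzz", "d1", title, mu=2500.0)
        assert math.isfinite(val)
        assert val < potential_F("gene", "d1", title, mu=2500.0)

    def test_empty_collection_rejected(self):
        from metaret.indexer import FieldIndex
        with pytest.raises(ValueError):
            potential_F("x", "d", FieldIndex(), 10.0)


class TestPairPotentials:
    def test_exact_bigram_beats_distant_terms(self):
        docs = [
            DatasetDoc("near", "a b " + "x " * 8, ""),
            DatasetDoc("far", "a x x x x x x x x b", ""),
        ]
        title, _ = build_index(docs, Stoplist.empty())
        cfg = CliqueConfig()
        near = potential_O(("a", "b"), "near", title, cfg)
        far = potential_O(("a", "b"), "far", title, cfg)
        assert near > far

    def test_never_cooccurring_pair_gets_floor(self, tiny_indices):
        title, _ = tiny_indices
        cfg = CliqueConfig()
        val = potential_U(("gene", "zzz"), "d1", title, cfg)
        assert math.isfinite(val)

    def test_collection_count_matches_full_scan(self):
        rng = np.random.default_rng(9)
        docs = random_corpus(rng, n_docs=30, vocab=8, doc_len=25)
        title, _ = build_index(docs, Stoplist.empty())
        cfg = CliqueConfig()
        for t1, t2 in [("v0", "v1"), ("v2", "v5"), ("v3", "v3")]:
            for kind, window in (("O", cfg.ordered_window),
                                 ("U", cfg.unordered_window)):
                counter = count_ordered if kind == "O" else count_unordered
                expected = sum(
                    counter(title.positions(t1, d), title.positions(t2, d), window)
                    for d in title.doc_length)
                assert pair_collection_count(t1, t2, title, kind, window) == expected


def brute_force_mrf(query, doc_id, indices, cfg, pos_weights=None):
    """Independent clique-sum oracle evaluated straight from the definition."""
    lam = ((lambda t: pos_weights.weights.get(t, pos_weights.weights["OTHER"]))
           if pos_weights else (lambda t: 1.0))
    total = 0.0
    for index, fw in zip(indices, cfg.field_weights):
        part = 0.0
        for term in query.terms:
            part += cfg.theta_F * lam(term.tag) * term.weight * potential_F(
                term.token, doc_id, index, cfg.dirichlet_mu)
        orig = [t for t in query.terms if not t.is_expansion]
        for a, b in zip(orig, orig[1:]):
            part += (cfg.theta_O * (lam(a.tag) + lam(b.tag)) / 2
                     * (a.weight + b.weight) / 2
                     * potential_O((a.token, b.token), doc_id, index, cfg))
        for i in range(len(orig)):
            for j in range(i + 1, len(orig)):
                a, b = orig[i], orig[j]
                part += (cfg.theta_U * (lam(a.tag) + lam(b.tag)) / 2
                         * (a.weight + b.weight) / 2
                         * potential_U((a.token, b.token), doc_id, index, cfg))
        total += fw * part
    return total


class TestScoring:
    def test_single_term_query_is_theta_f_potential(self):
        docs = [DatasetDoc("d1", "gene disease", ""), DatasetDoc("d2", "other", "")]
        indices = build_index(docs, Stoplist.empty())
        cfg = CliqueConfig(field_weights=(1.0, 0.0))
        scorer = Scorer(*indices, config=cfg)
        q = make_query(["gene"])
        expected = cfg.theta_F * potential_F("gene", "d1", indices[0],
                                             cfg.dirichlet_mu)
        assert math.isclose(scorer.score_mrf(q, "d1"), expected, rel_tol=1e-12)

    def test_matching_bigram_never_decreases_score(self):
        rng = np.random.default_rng(17)
        for trial in range(10):
            base_words = list(rng.choice([f"v{i}" for i in range(10)], size=20))
            with_bigram = base_words[:10] + ["qa", "qb"] + base_words[10:]
            docs = [DatasetDoc("plain", " ".join(base_words + ["x", "y"]), ""),
                    DatasetDoc("bigram", " ".join(with_bigram), "")]
            indices = build_index(docs, Stoplist.empty())
            scorer = Scorer(*indices)
            q = make_query(["qa", "qb"])
            assert scorer.score_mrf(q, "bigram") >= scorer.score_mrf(q, "plain")

    def test_matches_bruteforce_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(23)
        for trial in range(15):
            docs = random_corpus(rng, n_docs=12, vocab=10, doc_len=18)
            indices = build_index(docs, Stoplist.empty())
            cfg = CliqueConfig()
            scorer = Scorer(*indices, config=cfg)
            tokens = list(rng.choice([f"v{i}" for i in range(10)], size=3,
                                     replace=False))
            q = make_query(tokens, tags=["NN", "JJ", "VBD"])
            doc_id = f"d{rng.integers(0, 12)}"
            assert math.isclose(scorer.score_mrf(q, doc_id),
                                brute_force_mrf(q, doc_id, indices, cfg),
                                rel_tol=1e-10)
            assert math.isclose(scorer.score_posmrf(q, doc_id),
                                brute_force_mrf(q, doc_id, indices, cfg,
                                                PosWeights()),
                                rel_tol=1e-10)

    def test_all_other_tags_score_zero(self, tiny_indices):
        scorer = Scorer(*tiny_indices)
        q = make_query(["gene", "disease"], tags=["CD", "IN"])
        assert scorer.score_posmrf(q, "d1") == 0.0

    def test_empty_query_scores_zero(self, tiny_indices):
        scorer = Scorer(*tiny_indices)
        assert scorer.score_posmrf(TaggedQuery("q", []), "d1") == 0.0


class TestTfidf:
    def test_identical_doc_scores_one(self):
        docs = [DatasetDoc("d1", "alpha beta gamma", ""),
                DatasetDoc("d2", "delta epsilon", ""),
                DatasetDoc("d3", "zeta eta theta", "")]
        indices = build_index(docs, Stoplist.empty())
        scorer = Scorer(*indices, config=CliqueConfig(field_weights=(1.0, 0.0)))
        q = make_query(["alpha", "beta", "gamma"])
        assert math.isclose(scorer.score_tfidf(q, "d1"), 1.0, abs_tol=1e-9)

    def test_disjoint_doc_scores_zero(self):
        docs = [DatasetDoc("d1", "alpha beta", ""), DatasetDoc("d2", "x y", "")]
        indices = build_index(docs, Stoplist.empty())
        scorer = Scorer(*indices)
        q = make_query(["alpha", "beta"])
        assert scorer.score_tfidf(q, "d2") == 0.0

    def test_matches_dense_cosine_oracle(self):
        rng = np.random.default_rng(31)
        for trial in range(10):
            docs = random_corpus(rng, n_docs=15, vocab=12, doc_len=20)
            indices = build_index(docs, Stoplist.empty())
            cfg = CliqueConfig(field_weights=(1.0, 0.0))
            scorer = Scorer(*indices, config=cfg)
            title = indices[0]
            vocab = sorted(title.postings)
            n = title.doc_count
            idf = np.array([math.log(n / title.df(t)) for t in vocab])
            tokens = list(rng.choice([f"v{i}" for i in range(12)], size=3,
                                     replace=False))
            qtf = np.array([tokens.count(t) for t in vocab], dtype=float)
            qvec = np.where(qtf > 0, (1 + np.log(np.maximum(qtf, 1e-12))) * idf, 0.0)
            doc_id = f"d{rng.integers(0, 15)}"
            dtf = np.array([title.tf(t, doc_id) for t in vocab], dtype=float)
            dvec = np.where(dtf > 0, (1 + np.log(np.maximum(dtf, 1e-12))) * idf, 0.0)
            qn, dn = np.linalg.norm(qvec), np.linalg.norm(dvec)
            expected = float(qvec @ dvec / (qn * dn)) if qn and dn else 0.0
            q = make_query(tokens)
            assert math.isclose(scorer.score_tfidf(q, doc_id), expected,
                                abs_tol=1e-9)


class TestRetrieve:
    def test_k_larger_than_matches(self, tiny_indices):
        scorer = Scorer(*tiny_indices)
        q = make_query(["gene"])
        out = scorer.retrieve(q, "posmrf", k=100)
        assert len(out) == 1 and out.items[0][0] == "d1"

    def test_planted_relevant_doc_ranks_first_under_every_model(self):
        rng = np.random.default_rng(41)
        filler = random_corpus(rng, n_docs=20, vocab=10, doc_len=15)
        planted = DatasetDoc("win", "qa qb qc qa qb qc", "qa qb qc")
        indices = build_index(filler + [planted], Stoplist.empty())
        q = make_query(["qa", "qb", "qc"])
        for model in ("tfidf", "ql", "mrf", "posmrf"):
            out = Scorer(*indices).retrieve(q, model, k=5)
            assert out.items[0][0] == "win", model

    def test_deterministic(self, tiny_indices):
        scorer = Scorer(*tiny_indices)
        q = make_query(["gene", "disease"])
        a = scorer.retrieve(q, "mrf", 10)
        b = scorer.retrieve(q, "mrf", 10)
        assert a.items == b.items

    def test_unknown_model_rejected(self, tiny_indices):
        with pytest.raises(ValueError, match="unknown model"):
            Scorer(*tiny_indices).retrieve(make_query(["gene"]), "bm25", 10)

    def test_k_validation(self, tiny_indices):
        with pytest.raises(ValueError):
            Scorer(*tiny_indices).retrieve(make_query(["gene"]), "mrf", 0)


class TestReductions:
    def test_posmrf_with_unit_lambdas_equals_mrf(self):
        rng = np.random.default_rng(53)
        for trial in range(10):
            docs = random_corpus(rng, n_docs=20, vocab=15, doc_len=20)
            indices = build_index(docs, Stoplist.empty())
            q = tag_query(random_query(rng, vocab=15, n_terms=4),
                          stoplist=Stoplist.empty())
            mrf = Scorer(*indices).retrieve(q, "mrf", 50)
            pos = Scorer(*indices, pos_weights=UNIFORM_POS).retrieve(q, "posmrf", 50)
            assert mrf.items == pos.items

    def test_mrf_with_theta_100_equals_ql(self):
        rng = np.random.default_rng(59)
        for trial in range(10):
            docs = random_corpus(rng, n_docs=20, vocab=15, doc_len=20)
            indices = build_index(docs, Stoplist.empty())
            cfg = CliqueConfig(theta_F=1.0, theta_O=0.0, theta_U=0.0)
            q = tag_query(random_query(rng, vocab=15, n_terms=4),
                          stoplist=Stoplist.empty())
            mrf = Scorer(*indices, config=cfg).retrieve(q, "mrf", 50)
            ql = Scorer(*indices).retrieve(q, "ql", 50)
            assert mrf.items == ql.items


class TestTagQuery:
    def test_from_raw_query(self):
        q = tag_query(RawQuery("q1", "Find data on T-cell homeostasis"))
        assert [t.token for t in q.terms] == ["data", "t-cell", "homeostasis"]
        assert all(t.weight == 1.0 for t in q.terms)

    def test_from_weighted_query(self):
        from metaret.expansion import WeightedQuery
        wq = WeightedQuery("q1", ["gene", "disease"], ["illness"], 0.9, 0.1)
        q = tag_query("ignored", weighted=wq, query_id="q1")
        assert [t.weight for t in q.originals] == [0.9, 0.9]
        assert [t.token for t in q.expansions] == ["illness"]
        assert q.expansions[0].weight == 0.1
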