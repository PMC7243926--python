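import math

import numpy as np
import pytest

from conftest import random_qrels
from metaret.corpus_io import SampledQrels, write_qrels, write_run
from metaret.metrics import (average_precision, evaluate, evaluate_run, inf_ap,
                             inf_ndcg, ndcg_at_k, precision_at_k)
from metaret.synthetic import sample_qrels


def qrels_of(grades: dict[str, int], qid: str = "q") -> SampledQrels:
    return SampledQrels(judgments={(qid, d): g for d, g in grades.items()})


# --- independent brute-force oracles (definitional implementations) ---------

def oracle_ap(ranking, grades, threshold=1):
    rel = {d for d, g in grades.items() if g >= threshold}
    if not rel:
        return float("nan")
    total, hits = 0.0, 0
    for rank, doc in enumerate(ranking, 1):
        if doc in rel:
            hits += 1
            total += hits / rank
    return total / len(rel)


def oracle_p_at_k(ranking, grades, k, threshold):
    return sum(1 for d in ranking[:k] if grades.get(d, 0) >= threshold) / k


def oracle_ndcg(ranking, grades, k):
    def dcg(gains):
        return sum(g / math.log2(i + 1) for i, g in enumerate(gains, 1))
    ideal = dcg(sorted(grades.values(), reverse=True)[:k])
    if ideal == 0:
        return float("nan")
    return dcg([grades.get(d, 0) for d in ranking[:k]]) / ideal


class TestAveragePrecision:
    def test_perfect_ranking(self):
        q = qrels_of({"a": 2, "b": 1})
        assert average_precision(["a", "b"], q, "q") == 1.0

    def test_hand_example(self):
        q = qrels_of({"a": 1, "b": 1, "x": 0, "y": 0})
        ap = average_precision(["x", "a", "y", "b"], q, "q")
        assert ap == pytest.approx((1 / 2 + 2 / 4) / 2)

    def test_no_relevant_docs_gives_nan(self):
        q = qrels_of({"a": 0})
        assert math.isnan(average_precision(["a"], q, "q"))

    def test_threshold_two_excludes_partial(self):
        q = qrels_of({"a": 1, "b": 2})
        assert average_precision(["a", "b"], q, "q", rel_threshold=2) == \
            pytest.approx(1 / 2)

    def test_matches_oracle_on_fuzzed_instances(self):
        rng = np.random.default_rng(101)
        for _ in range(200):
            q = random_qrels(rng)
            ranking = [f"d{i}" for i in rng.permutation(100)[:50]]
            grades = q.grades_for("q")
            expected = oracle_ap(ranking, grades)
            got = average_precision(ranking, q, "q")
            if math.isnan(expected):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)


class TestPrecisionAtK:
    def test_counts(self):
        grades = {f"d{i}": g for i, g in enumerate([2, 1, 0, 0, 0, 0, 0, 0, 0, 0])}
        q = qrels_of(grades)
        ranking = [f"d{i}" for i in range(10)]
        assert precision_at_k(ranking, q, "q", 10, True) == pytest.approx(0.2)
        assert precision_at_k(ranking, q, "q", 10, False) == pytest.approx(0.1)

    def test_empty_ranking(self):
        assert precision_at_k([], qrels_of({"a": 2}), "q", 10) == 0.0

    def test_short_list_padded_as_nonrelevant(self):
        q = qrels_of({"a": 2})
        assert precision_at_k(["a"], q, "q", 10, True) == pytest.approx(0.1)

    def test_plus_partial_dominates(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            q = random_qrels(rng)
            ranking = [f"d{i}" for i in rng.permutation(100)[:20]]
            assert precision_at_k(ranking, q, "q", 10, True) >= \
                precision_at_k(ranking, q, "q", 10, False)


class TestNdcg:
    def test_perfect_ordering(self):
        q = qrels_of({"a": 2, "b": 1, "c": 0})
        assert ndcg_at_k(["a", "b", "c"], q, "q", 10) == pytest.approx(1.0)

    def test_hand_example(self):
        q = qrels_of({"a": 2, "b": 0})
        val = ndcg_at_k(["b", "a"], q, "q", 2)
        assert val == pytest.approx(1 / math.log2(3))

    def test_all_zero_grades_nan(self):
        q = qrels_of({"a": 0})
        assert math.isnan(ndcg_at_k(["a"], q, "q", 10))

    def test_matches_oracle_on_fuzzed_instances(self):
        rng = np.random.default_rng(103)
        for _ in range(200):
            q = random_qrels(rng)
            ranking = [f"d{i}" for i in rng.permutation(100)[:30]]
            expected = oracle_ndcg(ranking, q.grades_for("q"), 10)
            got = ndcg_at_k(ranking, q, "q", 10)
            if math.isnan(expected):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)


class TestInferredMeasures:
    def test_reduce_to_classical_under_complete_judgments(self):
        rng = np.random.default_rng(107)
        for _ in range(100):
            q = random_qrels(rng)
            ranking = [f"d{i}" for i in rng.permutation(100)[:50]]
            ap = average_precision(ranking, q, "q")
            if not math.isnan(ap):
                assert abs(inf_ap(ranking, q, "q") - ap) <= 1e-6
            nd = ndcg_at_k(ranking, q, "q", 10)
            if not math.isnan(nd):
                assert abs(inf_ndcg(ranking, q, "q", 10) - nd) <= 1e-6

    def test_rank_one_relevant_contributes_one(self):
        q = qrels_of({"a": 2})
        assert inf_ap(["a"], q, "q") == pytest.approx(1.0)

    def test_sample_without_relevant_gives_zero_ndcg(self):
        q = SampledQrels(judgments={("q", "a"): 0},
                         strata={("q", "a"): "s"},
                         stratum_meta={("q", "s"): (4, 1)})
        assert inf_ndcg(["a", "b"], q, "q", 10) == 0.0

    def test_missing_meta_falls_back_to_complete(self):
        q = qrels_of({"a": 2, "b": 0})
        assert q.weight_of("q", "a") == 1.0

    def test_sampling_weights_used(self):
        full = SampledQrels(
            judgments={("q", "a"): 2, ("q", "b"): 2, ("q", "c"): 0, ("q", "d"): 0},
            strata={("q", x): "s" for x in "abcd"},
            stratum_meta={("q", "s"): (4, 2)})
        sampled = SampledQrels(
            judgments={("q", "a"): 2, ("q", "c"): 0},
            strata={("q", "a"): "s", ("q", "c"): "s"},
            stratum_meta={("q", "s"): (4, 2)})
        # estimated relevant = 2 (weight 2 x 1 sampled relevant)
        val = inf_ap(["a", "c"], sampled, "q")
        assert val == pytest.approx(2.0 * 1.0 / 2.0)

    def test_unbiasedness_small_monte_carlo(self):
        rng = np.random.default_rng(42)
        n_docs = 200
        judged = rng.choice(n_docs, size=120, replace=False)
        grades = rng.choice([0, 0, 0, 1, 2], size=120)
        judgments = {("q", f"d{i}"): int(g) for i, g in zip(judged, grades)}
        full = SampledQrels(judgments=judgments,
                            strata={k: "all" for k in judgments},
                            stratum_meta={("q", "all"): (120, 120)})
        ranking = [f"d{i}" for i in rng.permutation(n_docs)]
        true_ap = average_precision(ranking, full, "q")
        aps = [inf_ap(ranking, sample_qrels(full, 0.5, seed=s), "q")
               for s in range(100)]
        assert abs(float(np.mean(aps)) - true_ap) < 0.03


class TestEvaluate:
    def make_run(self):
        judgments = {}
        rankings = {}
        rng = np.random.default_rng(11)
        for qi in range(5):
            qid = f"q{qi}"
            for d in range(30):
                judgments[(qid, f"d{d}")] = int(rng.choice([0, 0, 1, 2]))
            rankings[qid] = [f"d{i}" for i in rng.permutation(60)[:40]]
        return rankings, SampledQrels(judgments=judgments)

    def test_ideal_run_has_perfect_ndcg(self):
        rankings, qrels = self.make_run()
        ideal = {qid: sorted(qrels.grades_for(qid),
                             key=lambda d: -qrels.grades_for(qid)[d])
                 for qid in rankings}
        result = evaluate(ideal, qrels)
        for row in result.per_query.values():
            assert row["NDCG@10"] == pytest.approx(1.0)

    def test_deterministic(self):
        rankings, qrels = self.make_run()
        a = evaluate(rankings, qrels)
        b = evaluate(rankings, qrels)
        assert a.per_query == b.per_query and a.mean == b.mean

    def test_hand_assembled_table(self):
        rankings, qrels = self.make_run()
        result = evaluate(rankings, qrels)
        for qid, ranking in rankings.items():
            grades = qrels.grades_for(qid)
            assert result.per_query[qid]["MAP"] == pytest.approx(
                oracle_ap(ranking, grades), abs=1e-12)
            assert result.per_query[qid]["P@10(+partial)"] == pytest.approx(
                oracle_p_at_k(ranking, grades, 10, 1))
            assert result.per_query[qid]["NDCG@10"] == pytest.approx(
                oracle_ndcg(ranking, grades, 10), abs=1e-12)

    def test_no_shared_queries_fatal(self):
        with pytest.raises(ValueError, match="share no queries"):
            evaluate({"qx": ["d1"]}, qrels_of({"a": 1}, qid="qy"))

    def test_evaluate_run_from_files(self, tmp_path):
        rankings, qrels = self.make_run()
        run_path = tmp_path / "r.run"
        qrels_path = tmp_path / "q.qrels"
        write_run({qid: [(d, float(100 - i)) for i, d in enumerate(docs)]
                   for qid, docs in rankings.items()}, "t", run_path)
        write_qrels(qrels, qrels_path)
        result = evaluate_run(run_path, qrels_path, stratified=True,
                              out_path=tmp_path / "eval.tsv")
        direct = evaluate(rankings, qrels)
        for qid in rankings:
            for metric, value in direct.per_query[qid].items():
                assert result.per_query[qid][metric] == pytest.approx(value)
        tsv = (tmp_path / "eval.tsv").read_text()
        assert tsv.splitlines()[-1].startswith("all\t")
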