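"""Retrieval evaluation: MAP, P@10(+/-partial), NDCG@10, infAP and infNDCG.

Classical metrics treat unjudged retrieved documents as non-relevant.  The
inferred measures instead treat the judgments as a per-stratum random
sample of the judging pool: sampled judgments are weighted by the inverse
sampling rate (pool/sample) and precision above a rank is estimated from
the sampled documents seen so far.  With complete judgments both inferred
measures reduce to their classical counterparts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

from metaret.corpus_io import SampledQrels, read_qrels, read_run

logger = logging.getLogger(__name__)

EPSILON = 1e-5

METRIC_NAMES = ("infAP", "infNDCG", "NDCG@10", "P@10(+partial)",
                "P@10(-partial)", "MAP")


def _doc_ids(ranking) -> list[str]:
    if hasattr(ranking, "doc_ids"):
        return ranking.doc_ids()
    if ranking and isinstance(ranking[0], tuple):
        return [d for d, _s in ranking]
    return list(ranking)


def average_precision(ranking, qrels: SampledQrels, query_id: str,
                      rel_threshold: int = 1) -> float:
    """Mean precision at the ranks of relevant documents.

    Unretrieved relevant documents contribute 0; unjudged retrieved
    documents count as non-relevant.
    """
    if rel_threshold not in (1, 2):
        raise ValueError("rel_threshold must be 1 or 2")
    grades = qrels.grades_for(query_id)
    n_rel = sum(1 for g in grades.values() if g >= rel_threshold)
    if n_rel == 0:
        logger.warning("query %s has no relevant documents", query_id)
        return float("nan")
    hits = 0
    total = 0.0
    for rank, doc_id in enumerate(_doc_ids(ranking), 1):
        if grades.get(doc_id, 0) >= rel_threshold:
            hits += 1
            total += hits / rank
    return total / n_rel


def precision_at_k(ranking, qrels: SampledQrels, query_id: str, k: int = 10,
                   include_partial: bool = True) -> float:
    """Fraction of the top-k with grade >= 1 (+partial) or grade == 2 (-partial)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    grades = qrels.grades_for(query_id)
    threshold = 1 if include_partial else 2
    docs = _doc_ids(ranking)[:k]
    return sum(1 for d in docs if grades.get(d, 0) >= threshold) / k


def dcg(gains: list[float]) -> float:
    return sum(g / math.log2(rank + 1) for rank, g in enumerate(gains, 1))


def ndcg_at_k(ranking, qrels: SampledQrels, query_id: str, k: int = 10) -> float:
    """DCG@k with linear gain (= grade) over the ideal DCG@k of judged docs."""
    if k < 1:
        raise ValueError("k must be >= 1")
    grades = qrels.grades_for(query_id)
    ideal = dcg(sorted(grades.values(), reverse=True)[:k])
    if ideal == 0.0:
        logger.warning("query %s has ideal DCG 0", query_id)
        return float("nan")
    run = dcg([float(grades.get(d, 0)) for d in _doc_ids(ranking)[:k]])
    return run / ideal


def inf_ap(ranking, qrels: SampledQrels, query_id: str,
           rel_threshold: int = 1) -> float:
    """Sample-based expected average precision.

    For a sampled relevant document at rank k the expected precision is

        E[P@k] = 1/k + ((k-1)/k) * (judged_above/(k-1))
                     * ((rel_above + eps) / (judged_above + 2*eps))

    with judged/relevant counts weighted by inverse sampling rates, the
    contribution weighted likewise, and the sum scaled by the estimated
    total number of relevant documents.  Complete judgments reduce this to
    classical AP within epsilon.
    """
    grades = qrels.grades_for(query_id)
    est_rel = sum(qrels.weight_of(query_id, d)
                  for d, g in grades.items() if g >= rel_threshold)
    if est_rel == 0.0:
        logger.warning("query %s: no sampled relevant documents", query_id)
        return float("nan")
    judged_w = 0.0
    rel_w = 0.0
    total = 0.0
    for rank, doc_id in enumerate(_doc_ids(ranking), 1):
        if doc_id in grades:
            weight = qrels.weight_of(query_id, doc_id)
            if grades[doc_id] >= rel_threshold:
                if rank == 1:
                    expected = 1.0
                else:
                    above = min(judged_w, rank - 1.0)
                    expected = (1.0 / rank
                                + ((rank - 1.0) / rank) * (above / (rank - 1.0))
                                * ((rel_w + EPSILON) / (judged_w + 2.0 * EPSILON)))
                total += weight * expected
                rel_w += weight
            judged_w += weight
    return total / est_rel


def _ideal_dcg_from_counts(counts: dict[int, float], k: int | None) -> float:
    """Ideal DCG for (possibly fractional) estimated grade counts.

    Ranks are filled greedily with the highest grades; a fractional count
    contributes a proportional share of its grade at the boundary rank.
    """
    remaining = [[float(g), c] for g, c in sorted(counts.items(), reverse=True)
                 if g > 0 and c > 0]
    total = 0.0
    rank = 1
    while remaining and (k is None or rank <= k):
        need = 1.0
        gain = 0.0
        while remaining and need > 1e-12:
            g, c = remaining[0]
            take = min(c, need)
            gain += g * take
            need -= take
            remaining[0][1] -= take
            if remaining[0][1] <= 1e-12:
                remaining.pop(0)
        total += gain / math.log2(rank + 1)
        rank += 1
    return total


def inf_ndcg(ranking, qrels: SampledQrels, query_id: str,
             k_cut: int | None = None) -> float:
    """Inferred NDCG: inverse-sampling-rate weighted DCG over estimated ideal DCG."""
    grades = qrels.grades_for(query_id)
    counts: dict[int, float] = {}
    for d, g in grades.items():
        if g > 0:
            counts[g] = counts.get(g, 0.0) + qrels.weight_of(query_id, d)
    ideal = _ideal_dcg_from_counts(counts, k_cut)
    if ideal == 0.0:
        logger.warning("query %s: sample contains no relevant documents", query_id)
        return 0.0
    total = 0.0
    for rank, doc_id in enumerate(_doc_ids(ranking), 1):
        if k_cut is not None and rank > k_cut:
            break
        g = grades.get(doc_id, 0)
        if g > 0:
            total += qrels.weight_of(query_id, doc_id) * g / math.log2(rank + 1)
    return min(1.0, total / ideal)


@dataclass
class EvalResult:
    per_query: dict[str, dict[str, float]] = field(default_factory=dict)
    mean: dict[str, float] = field(default_factory=dict)
    judged_retrieved: dict[str, int] = field(default_factory=dict)
    unjudged_retrieved: dict[str, int] = field(default_factory=dict)

    def to_tsv(self) -> str:
        lines = ["query_id\t" + "\t".join(METRIC_NAMES)]
        for qid in sorted(self.per_query):
            row = self.per_query[qid]
            lines.append(qid + "\t" + "\t".join(
                f"{row[m]:.4f}" if not math.isnan(row[m]) else "NA"
                for m in METRIC_NAMES))
        lines.append("all\t" + "\t".join(
            f"{self.mean[m]:.4f}" for m in METRIC_NAMES))
        return "\n".join(lines) + "\n"


def evaluate(rankings: dict[str, list], qrels: SampledQrels,
             map_threshold: int = 1) -> EvalResult:
    """All six metrics per query plus means over queries with >=1 relevant doc."""
    shared = [q for q in qrels.query_ids() if q in rankings]
    if not shared:
        raise ValueError("run and qrels share no queries")
    result = EvalResult()
    for qid in shared:
        ranking = rankings[qid]
        grades = qrels.grades_for(qid)
        docs = _doc_ids(ranking)
        result.judged_retrieved[qid] = sum(1 for d in docs if d in grades)
        result.unjudged_retrieved[qid] = len(docs) - result.judged_retrieved[qid]
        result.per_query[qid] = {
            "infAP": inf_ap(ranking, qrels, qid),
            "infNDCG": inf_ndcg(ranking, qrels, qid),
            "NDCG@10": ndcg_at_k(ranking, qrels, qid, 10),
            "P@10(+partial)": precision_at_k(ranking, qrels, qid, 10, True),
            "P@10(-partial)": precision_at_k(ranking, qrels, qid, 10, False),
            "MAP": average_precision(ranking, qrels, qid, map_threshold),
        }
    for metric in METRIC_NAMES:
        vals = [row[metric] for row in result.per_query.values()
                if not math.isnan(row[metric])]
        result.mean[metric] = sum(vals) / len(vals) if vals else float("nan")
    return result


def evaluate_run(run_path: str | Path, qrels_path: str | Path,
                 stratified: bool = False, out_path: str | Path | None = None,
                 map_threshold: int = 1) -> EvalResult:
    """Evaluate a TREC run file against a qrels file; optionally write a TSV."""
    runs = read_run(run_path)
    qrels = read_qrels(qrels_path, stratified=stratified)
    if not qrels.judgments:
        raise ValueError(f"qrels file {qrels_path} is empty")
    rankings = {qid: [r.doc_id for r in records] for qid, records in runs.items()}
    result = evaluate(rankings, qrels, map_threshold=map_threshold)
    if out_path is not None:
        Path(out_path).write_text(result.to_tsv(), encoding="utf-8")
    return result
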