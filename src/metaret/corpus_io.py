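"""Readers and writers for every on-disk artifact.

Dataset metadata (JSON lines, JSON array, or a directory of JSON files),
query files, qrels (plain and stratified dialects), TREC-format run files,
entity annotations and entity dictionaries (TSV).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from metaret.entities import EntityDictionary, EntityMention

logger = logging.getLogger(__name__)

DEFAULT_FIELD_MAP = {
    "doc_id": "_id",
    "title": "metadata.title",
    "description": "metadata.description",
}


@dataclass(frozen=True)
class DatasetDoc:
    """One metadata record: an identifier plus raw title/description text."""

    doc_id: str
    title: str = ""
    description: str = ""


@dataclass(frozen=True)
class RawQuery:
    query_id: str
    text: str


@dataclass
class RunRecord:
    query_id: str
    doc_id: str
    rank: int
    score: float
    tag: str


@dataclass
class SampledQrels:
    """Graded judgments, optionally with per-stratum sampling metadata.

    ``judgments`` maps ``(query_id, doc_id)`` to a grade in {0, 1, 2}.
    ``strata`` maps each judged pair to a stratum label and ``stratum_meta``
    maps ``(query_id, stratum)`` to ``(pool_size, sample_size)``; when the
    sample equals the pool the judgments are complete and inferred measures
    reduce to their classical counterparts.
    """

    judgments: dict[tuple[str, str], int] = field(default_factory=dict)
    strata: dict[tuple[str, str], str] | None = None
    stratum_meta: dict[tuple[str, str], tuple[int, int]] | None = None

    def query_ids(self) -> list[str]:
        return sorted({q for q, _ in self.judgments})

    def grades_for(self, query_id: str) -> dict[str, int]:
        return {d: g for (q, d), g in self.judgments.items() if q == query_id}

    def stratum_of(self, query_id: str, doc_id: str) -> str:
        if self.strata is None:
            return "all"
        return self.strata.get((query_id, doc_id), "all")

    def weight_of(self, query_id: str, doc_id: str) -> float:
        """Inverse sampling rate (pool/sample) for a judged pair; 1.0 if complete."""
        if self.stratum_meta is None:
            return 1.0
        meta = self.stratum_meta.get((query_id, self.stratum_of(query_id, doc_id)))
        if meta is None:
            return 1.0
        pool, sample = meta
        return pool / sample if sample > 0 else 1.0

    def validate(self) -> None:
        for (q, d), g in self.judgments.items():
            if g not in (0, 1, 2):
                raise ValueError(f"grade {g} for ({q},{d}) outside {{0,1,2}}")
        if self.strata is not None:
            for pair in self.judgments:
                if pair not in self.strata:
                    raise ValueError(f"judged pair {pair} has no stratum")
        if self.stratum_meta is not None:
            for key, (pool, sample) in self.stratum_meta.items():
                if sample > pool:
                    raise ValueError(f"sample > pool for stratum {key}")


def _get_path(record: dict, dotted: str):
    cur = record
    for part in dotted.split("."):
        if not isinstance(cur, dict) or part not in cur:
            return None
        cur = cur[part]
    return cur


def load_datasets(path: str | Path,
                  field_map: dict[str, str] | None = None,
                  ) -> tuple[list[DatasetDoc], int]:
    """Load every dataset record under ``path``; returns (docs, warning_count).

    Records with a missing/empty id, malformed JSON lines, and duplicate ids
    are skipped and counted as warnings.  Missing title/description become
    empty strings.
    """
    field_map = field_map or DEFAULT_FIELD_MAP
    path = Path(path)
    if not path.exists():
        raise IOError(f"dataset path does not exist: {path}")

    def iter_records() -> Iterator:
        if path.is_dir():
            for name in sorted(os.listdir(path)):
                if not name.endswith(".json"):
                    continue
                with open(path / name, encoding="utf-8") as fh:
                    try:
                        yield json.load(fh)
                    except json.JSONDecodeError:
                        yield _MALFORMED
        else:
            with open(path, encoding="utf-8") as fh:
                first = fh.read(1)
                fh.seek(0)
                if first == "[":
                    for rec in json.load(fh):
                        yield rec
                else:
                    for line in fh:
                        line = line.strip()
                        if not line:
                            continue
                        try:
                            yield json.loads(line)
                        except json.JSONDecodeError:
                            yield _MALFORMED

    docs: list[DatasetDoc] = []
    seen: set[str] = set()
    warnings = 0
    for rec in iter_records():
        if rec is _MALFORMED or not isinstance(rec, dict):
            warnings += 1
            logger.warning("skipping malformed record")
            continue
        doc_id = _get_path(rec, field_map["doc_id"])
        if doc_id is None or str(doc_id) == "":
            warnings += 1
            logger.warning("skipping record with missing id")
            continue
        doc_id = str(doc_id)
        if doc_id in seen:
            warnings += 1
            logger.warning("skipping duplicate doc_id %s", doc_id)
            continue
        seen.add(doc_id)
        title = _get_path(rec, field_map["title"]) or ""
        description = _get_path(rec, field_map["description"]) or ""
        docs.append(DatasetDoc(doc_id, str(title), str(description)))
    return docs, warnings


_MALFORMED = object()


def read_datasets(path, field_map=None) -> Iterator[DatasetDoc]:
    docs, _ = load_datasets(path, field_map)
    yield from docs


def write_datasets(docs: Iterable[DatasetDoc], path: str | Path,
                   field_map: dict[str, str] | None = None) -> None:
    """Write docs as JSON lines in the shape ``field_map`` describes."""
    field_map = field_map or DEFAULT_FIELD_MAP

    def put(record: dict, dotted: str, value) -> None:
        parts = dotted.split(".")
        cur = record
        for p in parts[:-1]:
            cur = cur.setdefault(p, {})
        cur[parts[-1]] = value

    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            rec: dict = {}
            put(rec, field_map["doc_id"], doc.doc_id)
            put(rec, field_map["title"], doc.title)
            put(rec, field_map["description"], doc.description)
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_queries(path: str | Path) -> list[RawQuery]:
    """One query per line: ``query_id<TAB or space>text``."""
    queries: list[RawQuery] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if "\t" in line:
                qid, text = line.split("\t", 1)
            else:
                qid, _, text = line.partition(" ")
            qid, text = qid.strip(), text.strip()
            if not qid or not text:
                raise ValueError(f"malformed query line: {line!r}")
            if qid in seen:
                raise ValueError(f"duplicate query_id {qid}")
            seen.add(qid)
            queries.append(RawQuery(qid, text))
    return queries


def write_queries(queries: Iterable[RawQuery], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for q in queries:
            fh.write(f"{q.query_id}\t{q.text}\n")


def read_qrels(path: str | Path, stratified: bool = False) -> SampledQrels:
    """Parse TREC qrels: ``qid col2 docid grade`` (col2 = stratum if stratified).

    Duplicate pairs resolve last-wins with a warning.  If a sidecar
    ``<path>.meta.json`` exists it supplies per-stratum pool/sample sizes;
    otherwise the judgments are treated as the complete pool.
    """
    judgments: dict[tuple[str, str], int] = {}
    strata: dict[tuple[str, str], str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            qid, col2, docid, grade_s = parts
            try:
                grade = int(grade_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer grade {grade_s!r}") from None
            if grade not in (0, 1, 2):
                raise ValueError(f"{path}:{lineno}: grade {grade} outside {{0,1,2}}")
            pair = (qid, docid)
            if pair in judgments:
                logger.warning("%s:%d: duplicate judgment for %s, last wins", path, lineno, pair)
            judgments[pair] = grade
            strata[pair] = col2 if stratified else "all"

    meta_path = Path(str(path) + ".meta.json")
    stratum_meta: dict[tuple[str, str], tuple[int, int]] = {}
    if meta_path.exists():
        with open(meta_path, encoding="utf-8") as fh:
            raw = json.load(fh)
        for key, (pool, sample) in raw.items():
            qid, _, stratum = key.partition("|")
            stratum_meta[(qid, stratum)] = (int(pool), int(sample))
    else:
        counts: dict[tuple[str, str], int] = {}
        for (qid, docid), _g in judgments.items():
            key = (qid, strata[(qid, docid)])
            counts[key] = counts.get(key, 0) + 1
        stratum_meta = {k: (n, n) for k, n in counts.items()}

    qrels = SampledQrels(judgments=judgments, strata=strata, stratum_meta=stratum_meta)
    qrels.validate()
    return qrels


def write_qrels(qrels: SampledQrels, path: str | Path) -> None:
    """Write the stratified qrels dialect (+ sampling sidecar when sampled)."""
    with open(path, "w", encoding="utf-8") as fh:
        for (qid, docid), grade in sorted(qrels.judgments.items()):
            stratum = qrels.stratum_of(qid, docid)
            fh.write(f"{qid} {stratum} {docid} {grade}\n")
    if qrels.stratum_meta and any(p != s for p, s in qrels.stratum_meta.values()):
        raw = {f"{q}|{st}": list(ps) for (q, st), ps in sorted(qrels.stratum_meta.items())}
        with open(str(path) + ".meta.json", "w", encoding="utf-8") as fh:
            json.dump(raw, fh, indent=1, sort_keys=True)


def write_run(lists, tag: str, path: str | Path, max_per_query: int = 1000) -> None:
    """Write ranked lists in TREC run format ``qid Q0 docid rank score tag``.

    ``lists`` maps query_id to an iterable of ``(doc_id, score)`` pairs (or a
    RankedList-like object with ``.items``).  Ties are broken by ascending
    doc_id; scores print with 6 fixed decimals; >1000 entries truncate with
    a warning.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for qid in sorted(lists):
            items = lists[qid]
            if hasattr(items, "items") and not isinstance(items, dict):
                items = items.items
            pairs = sorted(items, key=lambda p: (-p[1], p[0]))
            if len(pairs) > max_per_query:
                logger.warning("query %s: truncating %d entries to %d",
                               qid, len(pairs), max_per_query)
                pairs = pairs[:max_per_query]
            for rank, (docid, score) in enumerate(pairs, 1):
                fh.write(f"{qid} Q0 {docid} {rank} {score:.6f} {tag}\n")


def read_run(path: str | Path) -> dict[str, list[RunRecord]]:
    runs: dict[str, list[RunRecord]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns")
            qid, _q0, docid, rank, score, tag = parts
            runs.setdefault(qid, []).append(
                RunRecord(qid, docid, int(rank), float(score), tag))
    for records in runs.values():
        records.sort(key=lambda r: r.rank)
        for expect, rec in enumerate(records, 1):
            if rec.rank != expect:
                raise ValueError(f"ranks not contiguous for query {rec.query_id}")
    return runs


def read_annotations(path: str | Path, optional: bool = False,
                     ) -> dict[str, list[EntityMention]]:
    """Read a TSV of external entity annotations grouped per unit.

    Columns: ``unit_id start end surface entity_id semantic_type source``.
    """
    path = Path(path)
    if not path.exists():
        if optional:
            return {}
        raise IOError(f"annotation file does not exist: {path}")
    out: dict[str, list[EntityMention]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            unit_id, start_s, end_s, surface, entity_id, stype, source = parts
            start, end = int(start_s), int(end_s)
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            out.setdefault(unit_id, []).append(EntityMention(
                unit_id=unit_id, start=start, end=end, surface=surface,
                entity_id=entity_id, semantic_type=stype, source=source))
    return out


def write_annotations(mentions_by_unit: dict[str, list[EntityMention]],
                      path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for unit_id in sorted(mentions_by_unit):
            for m in sorted(mentions_by_unit[unit_id], key=lambda m: (m.start, m.end)):
                fh.write(f"{unit_id}\t{m.start}\t{m.end}\t{m.surface}\t"
                         f"{m.entity_id}\t{m.semantic_type}\t{m.source}\n")


def read_dictionary(path: str | Path) -> EntityDictionary:
    """Read a composite entity dictionary TSV.

    Columns: ``surface entity_id semantic_type source``.
    """
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            rows.append(tuple(parts))
    return EntityDictionary.from_rows(rows)


def write_dictionary(rows, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for surface, entity_id, stype, source in rows:
            fh.write(f"{surface}\t{entity_id}\t{stype}\t{source}\n")
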