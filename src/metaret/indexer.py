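"""Text preprocessing and the two-field positional inverted index.

Tokenization lowercases and splits on any non-alphanumeric character except
intra-token hyphens (so "t-cell" survives).  Stopwords are removed before
positional indexing; positions are 0-based over the post-stopword sequence.
"""

from __future__ import annotations

import bisect
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from metaret.corpus_io import DatasetDoc

# a token is a run of word characters (no underscore) possibly joined by
# single interior hyphens: "t-cell" is one token, "x--y" is two
TOKEN_RE = re.compile(r"[^\W_]+(?:-[^\W_]+)*", re.UNICODE)

QUERY_STOP_ADDITIONS = frozenset({"find", "search"})


def _base_stopwords() -> frozenset[str]:
    text = resources.files("metaret").joinpath("data/stopwords_en.txt").read_text("utf-8")
    return frozenset(w.strip() for w in text.splitlines() if w.strip())


@dataclass(frozen=True)
class Stoplist:
    terms: frozenset[str]
    source: str = "english"

    @classmethod
    def default(cls, query_mode: bool = False) -> "Stoplist":
        """The frozen base English list; query mode adds 'find' and 'search'."""
        terms = _base_stopwords()
        if query_mode:
            return cls(terms | QUERY_STOP_ADDITIONS, source="english+query")
        return cls(terms, source="english")

    @classmethod
    def empty(cls) -> "Stoplist":
        return cls(frozenset(), source="none")

    def __contains__(self, term: str) -> bool:
        return term in self.terms


def tokenize(text: str) -> list[str]:
    return TOKEN_RE.findall(text.lower())


def preprocess(text: str, stoplist: Stoplist | None = None,
               strip_punctuation: bool = True) -> list[str]:
    """Lowercase, tokenize and stop a raw string; order preserved.

    With ``strip_punctuation`` (the default) punctuation splits tokens except
    for intra-token hyphens; without it the text is only lowercased and
    whitespace-split.
    """
    if strip_punctuation:
        tokens = tokenize(text)
    else:
        tokens = text.lower().split()
    if stoplist is not None:
        tokens = [t for t in tokens if t not in stoplist]
    return tokens


class FieldIndex:
    """Positional inverted index for one metadata field plus collection stats."""

    def __init__(self) -> None:
        self.postings: dict[str, dict[str, list[int]]] = {}
        self.doc_length: dict[str, int] = {}
        self.collection_length: int = 0
        self._forward: dict[str, dict[str, int]] | None = None

    @property
    def doc_count(self) -> int:
        return len(self.doc_length)

    def add_document(self, doc_id: str, tokens: list[str]) -> None:
        if doc_id in self.doc_length:
            raise ValueError(f"duplicate doc_id {doc_id!r}")
        self.doc_length[doc_id] = len(tokens)
        self.collection_length += len(tokens)
        for pos, term in enumerate(tokens):
            self.postings.setdefault(term, {}).setdefault(doc_id, []).append(pos)
        self._forward = None

    def tf(self, term: str, doc_id: str) -> int:
        return len(self.postings.get(term, {}).get(doc_id, ()))

    def positions(self, term: str, doc_id: str) -> list[int]:
        return self.postings.get(term, {}).get(doc_id, [])

    def df(self, term: str) -> int:
        return len(self.postings.get(term, {}))

    def collection_tf(self, term: str) -> int:
        return sum(len(p) for p in self.postings.get(term, {}).values())

    def docs_with(self, term: str) -> Iterable[str]:
        return self.postings.get(term, {}).keys()

    def doc_terms(self, doc_id: str) -> dict[str, int]:
        """Forward view term->tf for one document (built lazily)."""
        if self._forward is None:
            fwd: dict[str, dict[str, int]] = {d: {} for d in self.doc_length}
            for term, per_doc in self.postings.items():
                for doc_id2, positions in per_doc.items():
                    fwd[doc_id2][term] = len(positions)
            self._forward = fwd
        return self._forward.get(doc_id, {})

    # --- serialization (versioned JSON) -------------------------------------
    def to_json(self) -> dict:
        return {
            "format": "metaret-field-index",
            "version": 1,
            "postings": self.postings,
            "doc_length": self.doc_length,
        }

    @classmethod
    def from_json(cls, data: dict) -> "FieldIndex":
        if data.get("format") != "metaret-field-index":
            raise ValueError("not a metaret field index")
        idx = cls()
        idx.postings = {t: dict(pd) for t, pd in data["postings"].items()}
        idx.doc_length = dict(data["doc_length"])
        idx.collection_length = sum(idx.doc_length.values())
        return idx

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "FieldIndex":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(json.load(fh))

    def check_invariants(self) -> None:
        assert sum(self.doc_length.values()) == self.collection_length
        for term, per_doc in self.postings.items():
            assert self.collection_tf(term) == sum(len(p) for p in per_doc.values())
            assert self.df(term) == len(per_doc)
            for positions in per_doc.values():
                assert positions == sorted(positions)


def build_index(docs: Iterable[DatasetDoc], stoplist: Stoplist | None = None,
                ) -> tuple[FieldIndex, FieldIndex]:
    """Index the title and description of every doc into two field indexes."""
    if stoplist is None:
        stoplist = Stoplist.default()
    title_idx, desc_idx = FieldIndex(), FieldIndex()
    for doc in docs:
        title_idx.add_document(doc.doc_id, preprocess(doc.title, stoplist))
        desc_idx.add_document(doc.doc_id, preprocess(doc.description, stoplist))
    return title_idx, desc_idx


def count_ordered(pos1: list[int], pos2: list[int], window: int) -> int:
    """Pairs (p1, p2) with p1 from ``pos1``, p2 from ``pos2`` and 0 < p2-p1 <= window."""
    if window < 1:
        raise ValueError("ordered window must be >= 1")
    total = 0
    for p1 in pos1:
        lo = bisect.bisect_right(pos2, p1)
        hi = bisect.bisect_right(pos2, p1 + window)
        total += hi - lo
    return total


def count_unordered(pos1: list[int], pos2: list[int], window: int) -> int:
    """Co-occurrence pairs with 0 < |p1 - p2| < window, either order."""
    if window < 2:
        raise ValueError("unordered window must be >= 2")
    total = 0
    for p1 in pos1:
        lo = bisect.bisect_right(pos2, p1 - window)
        hi = bisect.bisect_left(pos2, p1 + window)
        total += hi - lo
        # exclude the p1 == p2 degenerate pair
        i = bisect.bisect_left(pos2, p1)
        if i < len(pos2) and pos2[i] == p1:
            total -= 1
    return total
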