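"""Dictionary-based medical entity extraction and normalization.

Entities are located by greedy longest-match lookup of normalized token
n-grams against a composite dictionary, augmented with acronym detection,
and merged with optional external annotation sources under fixed priority
rules.  The normalized-identifier overlap between a query and a document is
the quantity the re-ranking stage consumes.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

SEMANTIC_TYPES = {
    "GENE", "CHEM", "DISO", "PROC", "ANAT", "SPEC", "PATH",
    "CELLCOMP", "BIOPROC", "OTHER",
}

#: priority order among annotation sources for gene/chemical/disease types
PRIORITY_GCD = ("pubtator", "becas", "dictionary")
#: priority order for every other semantic type
PRIORITY_OTHER = ("becas", "dictionary", "pubtator")

_GCD_TYPES = {"GENE", "CHEM", "DISO"}


@dataclass(frozen=True)
class EntityMention:
    """One normalized entity occurrence in a text unit (document or query)."""

    unit_id: str
    start: int          # 0-based, on the raw text
    end: int            # half-open
    surface: str
    entity_id: str
    semantic_type: str
    source: str = "dictionary"
    match_kind: str = "exact"

    def overlaps(self, other: "EntityMention") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class EntityDictionary:
    """Composite surface-form dictionary.

    ``entries`` maps a fully normalized surface key to the list of
    ``(entity_id, semantic_type, source_dictionary)`` records registered for
    it, in source-priority order.
    """

    entries: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)
    source_priority: list[str] = field(default_factory=list)

    def add(self, surface: str, entity_id: str, semantic_type: str, source: str) -> None:
        if semantic_type not in SEMANTIC_TYPES:
            semantic_type = "OTHER"
        key = normalize_surface(surface)
        if not key:
            return
        bucket = self.entries.setdefault(key, [])
        record = (entity_id, semantic_type, source)
        for i, (eid, _st, src) in enumerate(bucket):
            if src == source and eid == entity_id:
                bucket[i] = record
                break
        else:
            bucket.append(record)
        if source not in self.source_priority:
            self.source_priority.append(source)

    @classmethod
    def from_rows(cls, rows) -> "EntityDictionary":
        d = cls()
        for surface, entity_id, semantic_type, source in rows:
            d.add(surface, entity_id, semantic_type, source)
        return d

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def max_key_tokens(self) -> int:
        if not self.entries:
            return 1
        return max(len(k.split()) for k in self.entries)

    def lookup(self, key: str):
        """Best entry for a normalized key, honoring source registration order."""
        bucket = self.entries.get(key)
        if not bucket:
            return None
        for source in self.source_priority:
            for rec in bucket:
                if rec[2] == source:
                    return rec
        return bucket[0]


def _is_letter(ch: str) -> bool:
    return unicodedata.category(ch).startswith("L")


def _is_digit(ch: str) -> bool:
    return ch.isdigit()


def _norm_tokens_with_spans(text: str) -> list[tuple[str, int, int]]:
    """Normalized tokens of ``text`` with raw-text character spans.

    Tokens are maximal runs of letters or of digits (a letter<->digit
    boundary splits), lowercased.  Hyphens, parentheses and all other
    punctuation act as separators; parenthesis content is kept.
    """
    out: list[tuple[str, int, int]] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if _is_letter(ch):
            j = i
            while j < n and _is_letter(text[j]):
                j += 1
            out.append((text[i:j].lower(), i, j))
            i = j
        elif _is_digit(ch):
            j = i
            while j < n and _is_digit(text[j]):
                j += 1
            out.append((text[i:j], i, j))
            i = j
        else:
            i += 1
    return out


def normalize_surface(s: str) -> str:
    """Canonical dictionary key for a surface string.

    Lowercases, turns hyphens into spaces, splits letter/digit boundaries,
    strips parenthesis characters while keeping their content, and collapses
    whitespace.  Idempotent.

    >>> normalize_surface("bone morphogenetic protein-2")
    'bone morphogenetic protein 2'
    >>> normalize_surface("Gialpha(1)")
    'gialpha 1'
    """
    return " ".join(tok for tok, _s, _e in _norm_tokens_with_spans(s))


def dict_lookup(text: str, dictionary: EntityDictionary, unit_id: str = "") -> list[EntityMention]:
    """Greedy longest-match dictionary scan over normalized token n-grams.

    Returns non-overlapping mentions; at each position the longest matching
    key (up to ``max_ngram``) wins and the scan resumes after it.
    """
    if not dictionary.entries:
        return []
    max_n = min(8, dictionary.max_key_tokens)
    tokens = _norm_tokens_with_spans(text)
    mentions: list[EntityMention] = []
    i = 0
    while i < len(tokens):
        matched = False
        for n in range(min(max_n, len(tokens) - i), 0, -1):
            key = " ".join(t[0] for t in tokens[i:i + n])
            rec = dictionary.lookup(key)
            if rec is not None:
                start = tokens[i][1]
                end = tokens[i + n - 1][2]
                mentions.append(EntityMention(
                    unit_id=unit_id, start=start, end=end,
                    surface=text[start:end], entity_id=rec[0],
                    semantic_type=rec[1], source="dictionary",
                    match_kind="exact",
                ))
                i += n
                matched = True
                break
        if not matched:
            i += 1
    return mentions


def _valid_short_form(s: str) -> bool:
    if not 2 <= len(s) <= 10:
        return False
    letters = [c for c in s if _is_letter(c)]
    if not letters:
        return False
    return all(c.upper() == c for c in letters if c.isascii())


def _best_long_form(short: str, candidate: str) -> str | None:
    """Schwartz–Hearst style backward alignment of a short form.

    Every alphanumeric character of the short form must appear, in order,
    in the candidate long form; the first character must start a word.
    Returns the matched suffix of ``candidate`` (trimmed to a word start).
    """
    s_idx = len(short) - 1
    l_idx = len(candidate) - 1
    while s_idx >= 0:
        ch = short[s_idx].lower()
        if not (ch.isalnum() or not ch.isascii() and _is_letter(ch)):
            s_idx -= 1
            continue
        at_start = s_idx == 0 or not any(
            c.isalnum() for c in short[:s_idx]
        )
        while l_idx >= 0:
            ok = candidate[l_idx].lower() == ch
            if ok and at_start:
                ok = l_idx == 0 or not candidate[l_idx - 1].isalnum()
            if ok:
                break
            l_idx -= 1
        if l_idx < 0:
            return None
        l_idx -= 1
        s_idx -= 1
    start = l_idx + 1
    while start > 0 and candidate[start - 1].isalnum():
        start -= 1
    long_form = candidate[start:].strip()
    return long_form or None


def detect_acronyms(text: str) -> list[tuple[str, str]]:
    """Detect "long form (ACRONYM)" pairs.

    >>> detect_acronyms("multiple sclerosis (MS) patients")
    [('MS', 'multiple sclerosis')]
    """
    pairs: list[tuple[str, str]] = []
    i = 0
    while True:
        open_p = text.find("(", i)
        if open_p < 0:
            break
        close_p = text.find(")", open_p + 1)
        if close_p < 0:
            break
        short = text[open_p + 1:close_p].strip()
        i = close_p + 1
        if not _valid_short_form(short):
            continue
        before = text[:open_p].rstrip()
        # candidate window: at most min(|sf|+5, 2|sf|) preceding words
        words = before.split(" ")
        n_alnum = sum(1 for c in short if c.isalnum())
        max_words = min(n_alnum + 5, n_alnum * 2)
        candidate = " ".join(words[-max_words:]) if max_words > 0 else ""
        long_form = _best_long_form(short, candidate)
        if long_form and long_form.lower() != short.lower():
            pairs.append((short, long_form))
    return pairs


def _source_rank(mention: EntityMention) -> int:
    order = PRIORITY_GCD if mention.semantic_type in _GCD_TYPES else PRIORITY_OTHER
    try:
        return order.index(mention.source)
    except ValueError:
        return len(order)


def merge_annotations(per_source: dict[str, list[EntityMention]],
                      priority: tuple[str, ...] | None = None) -> list[EntityMention]:
    """Merge mention lists from several annotators into one non-overlapping list.

    For GENE/CHEM/DISO mentions pubtator beats becas beats the dictionary;
    for every other type becas beats the dictionary.  Within a source, exact
    matches beat partial ones, and longer spans beat shorter ones.
    """
    pool: list[EntityMention] = []
    for mentions in per_source.values():
        pool.extend(mentions)
    if priority is not None:
        def src_rank(m: EntityMention) -> int:
            try:
                return priority.index(m.source)
            except ValueError:
                return len(priority)
    else:
        src_rank = _source_rank

    def sort_key(m: EntityMention):
        return (src_rank(m), 0 if m.match_kind == "exact" else 1,
                -(m.end - m.start), m.start, m.entity_id)

    kept: list[EntityMention] = []
    for m in sorted(pool, key=sort_key):
        if not any(m.overlaps(k) for k in kept):
            kept.append(m)
    kept.sort(key=lambda m: (m.start, m.end))
    return kept


def extract_entities(text: str, dictionary: EntityDictionary, unit_id: str = "",
                     annotations: dict[str, list[EntityMention]] | None = None,
                     ) -> list[EntityMention]:
    """Full extraction pipeline for one text unit.

    Dictionary lookup + acronym inheritance, merged with any external
    annotation sources under the standard priority rules.
    """
    dict_mentions = dict_lookup(text, dictionary, unit_id=unit_id)
    # acronym inheritance: the short form inherits the long form's entry
    for short, long_form in detect_acronyms(text):
        key = normalize_surface(long_form)
        rec = dictionary.lookup(key)
        if rec is None:
            continue
        pos = 0
        while True:
            j = text.find("(" + short + ")", pos)
            if j < 0:
                break
            mention = EntityMention(
                unit_id=unit_id, start=j + 1, end=j + 1 + len(short),
                surface=short, entity_id=rec[0], semantic_type=rec[1],
                source="dictionary", match_kind="partial",
            )
            dict_mentions.append(mention)
            pos = j + 1
    per_source: dict[str, list[EntityMention]] = {"dictionary": dict_mentions}
    if annotations:
        for source, mentions in annotations.items():
            per_source.setdefault(source, []).extend(mentions)
    return merge_annotations(per_source)


def shared_entity_count(query_mentions, doc_mentions) -> int:
    """Number of unique entity identifiers shared between query and document."""
    q_ids = {m.entity_id for m in query_mentions}
    d_ids = {m.entity_id for m in doc_mentions}
    return len(q_ids & d_ids)
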