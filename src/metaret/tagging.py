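"""A small pluggable Penn-Treebank part-of-speech tagger.

The reference tagger is a deterministic lexicon + suffix-rule tagger for
general English.  It deliberately behaves like a generic newswire tagger on
keyword-style queries — e.g. it tags "search" as NN — because that failure
mode is part of what the POS-weighted ranking model is sensitive to.
A different tagger can be supplied anywhere a ``tagger`` callable is
accepted; the contract is one Penn tag per input token.
"""

from __future__ import annotations

from typing import Callable, Sequence

Tagger = Callable[[Sequence[str]], list[str]]

_CLOSED_CLASS = {
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "that": "DT",
    "these": "DT", "those": "DT", "all": "DT", "each": "DT", "every": "DT",
    "some": "DT", "any": "DT", "no": "DT", "both": "DT",
    "of": "IN", "in": "IN", "on": "IN", "for": "IN", "with": "IN",
    "at": "IN", "by": "IN", "from": "IN", "about": "IN", "into": "IN",
    "across": "IN", "between": "IN", "during": "IN", "after": "IN",
    "before": "IN", "under": "IN", "over": "IN", "through": "IN",
    "within": "IN", "without": "IN", "via": "IN", "per": "IN",
    "to": "TO",
    "and": "CC", "or": "CC", "but": "CC", "nor": "CC",
    "as": "IN", "than": "IN", "if": "IN", "whether": "IN",
    "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD",
    "be": "VB", "been": "VBN", "being": "VBG",
    "has": "VBZ", "have": "VBP", "had": "VBD",
    "do": "VBP", "does": "VBZ",
    "can": "MD", "could": "MD", "will": "MD", "would": "MD",
    "may": "MD", "might": "MD", "must": "MD", "should": "MD",
    "not": "RB", "also": "RB", "only": "RB", "very": "RB", "most": "RBS",
    "more": "RBR",
    "it": "PRP", "they": "PRP", "we": "PRP", "he": "PRP", "she": "PRP",
    "i": "PRP", "you": "PRP", "its": "PRP$", "their": "PRP$",
    "there": "EX", "when": "WRB", "where": "WRB", "how": "WRB", "why": "WRB",
    "which": "WDT", "what": "WP", "who": "WP",
}

# open-class words whose suffixes would otherwise mislead the rules
_LEXICON = {
    "data": "NNS", "types": "NNS", "obese": "JJ", "human": "JJ",
    "murine": "JJ", "bacterial": "JJ", "viral": "JJ", "clinical": "JJ",
    "large": "JJ", "small": "JJ", "new": "JJ", "novel": "JJ", "high": "JJ",
    "low": "JJ", "related": "VBN", "based": "VBN", "induced": "VBN",
    "derived": "VBN", "associated": "VBN", "expressed": "VBN",
    "find": "VB", "show": "VB", "use": "VB", "using": "VBG",
    "search": "NN", "gene": "NN", "protein": "NN", "cell": "NN",
    "cancer": "NN", "disease": "NN", "growth": "NN", "brain": "NN",
    "women": "NNS", "men": "NNS", "mice": "NNS", "patients": "NNS",
    "studies": "NNS", "datasets": "NNS", "databases": "NNS", "cells": "NNS",
}

_JJ_SUFFIXES = ("ous", "ble", "ive", "ar", "ic", "ical", "less", "ful",
                "ish", "like", "ant", "ent")
_NN_SUFFIXES_SINGULAR = ("ss", "us", "is", "sis", "osis", "itis")


def _tag_one(token: str) -> str:
    low = token.lower()
    if low in _CLOSED_CLASS:
        return _CLOSED_CLASS[low]
    if low in _LEXICON:
        return _LEXICON[low]
    if any(c.isdigit() for c in low) and not any(c.isalpha() for c in low):
        return "CD"
    if token[:1].isupper() and len(token) > 1:
        return "NNP"
    if low.endswith("ly") and len(low) > 3:
        return "RB"
    if low.endswith("ing") and len(low) > 5:
        return "VBG"
    if low.endswith("ed") and len(low) > 4:
        return "VBN"
    if low.endswith("ies") and len(low) > 4:
        return "NNS"
    if low.endswith("s") and len(low) > 3 and not low.endswith(_NN_SUFFIXES_SINGULAR):
        return "NNS"
    for suf in _JJ_SUFFIXES:
        if low.endswith(suf) and len(low) > len(suf) + 2:
            return "JJ"
    return "NN"


def rule_tagger(tokens: Sequence[str]) -> list[str]:
    return [_tag_one(t) for t in tokens]


def pos_tag(tokens: Sequence[str], tagger: Tagger | None = None) -> list[str]:
    """Tag tokens with Penn-Treebank tags; exactly one tag per token."""
    if not tokens:
        raise ValueError("cannot tag an empty token list")
    if tagger is None:
        tagger = rule_tagger
    tags = tagger(tokens)
    if len(tags) != len(tokens):
        raise RuntimeError("tagger returned a tag list of the wrong length")
    return tags
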