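"""Entity-overlap re-ranking of a retrieved list.

Every document in the top list is re-scored as

    s' = s_max * n_D + s_D

where n_D is the number of unique entity identifiers the document shares
with the query and s_max is the score of the rank-1 document.  Because the
dependence models score in the log domain (negative values), scores are
first shifted by a per-query constant (subtract the minimum, add 1) so all
base scores are positive; the shift preserves order within each n_D
stratum and restores the intended dominance of entity overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from metaret.ranking import RankedList


@dataclass
class RerankInput:
    ranked: RankedList
    n: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.n.values()):
            raise ValueError("entity-overlap counts must be >= 0")

    @property
    def s_max(self) -> float:
        if not self.ranked.items:
            raise ValueError("ranked list is empty")
        return self.ranked.items[0][1]


def rerank(inp: RerankInput, final_k: int = 1000) -> RankedList:
    """Re-score by entity overlap and return the top ``final_k`` documents."""
    if final_k < 1:
        raise ValueError("final_k must be >= 1")
    items = inp.ranked.items
    if not items:
        return RankedList(inp.ranked.query_id, [])
    min_score = min(s for _d, s in items)
    shift = (1.0 - min_score) if min_score <= 0.0 else 0.0
    shifted = [(d, s + shift) for d, s in items]
    s_max = max(s for _d, s in shifted)
    rescored = [(d, s_max * inp.n.get(d, 0) + s) for d, s in shifted]
    rescored.sort(key=lambda p: (-p[1], p[0]))
    return RankedList(inp.ranked.query_id, rescored[:final_k])
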