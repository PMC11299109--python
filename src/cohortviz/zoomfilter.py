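"""Score-based semantic zoom.

Zoomed out, only the highest-scored items (e.g. variants ranked by CADD) are
drawn; zooming in raises the display budget proportionally, so lower-scored
items appear progressively, like labels on a slippy map.  The coupling is a
count budget: at zoom level ``z`` the window may show at most
``ceil(budget × z)`` items, filled in descending score order with a
deterministic tie-break on (position, id).

The visible set is nested: every item visible at zoom ``z`` stays visible at
any ``z' ≥ z`` over the same window contents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Sequence

__all__ = ["ScoredItem", "visible_items"]


@dataclass(frozen=True)
class ScoredItem:
    id: Any
    position: float
    score: float


def visible_items(items: Sequence[ScoredItem], zoom_level: float,
                  budget: int) -> list[ScoredItem]:
    """The ``min(n, ceil(budget × zoomLevel))`` highest-scored items.

    Ties in score are broken by position, then id, so the selection is a
    pure function of the inputs.
    """
    if zoom_level < 1:
        raise ValueError("zoom level must be >= 1")
    if budget < 1:
        raise ValueError("budget must be >= 1")
    for item in items:
        if not math.isfinite(item.score):
            raise ValueError(f"non-finite score on item {item.id!r}")
    k = min(len(items), math.ceil(budget * zoom_level))
    ranked = sorted(items, key=lambda it: (-it.score, it.position, str(it.id)))
    return ranked[:k]
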