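"""Instrument definitions: the 10-item CES-D short form and the five-item
Internet-use-purpose checklist.

The canonical node order is fixed once here (De1..De10 then In1..In5) and every
downstream matrix, table and file uses it.  CES-D items 5 and 8 are positively
worded ("hopeful about the future", "happy") and are reverse-scored before
summation; the total ranges 0-30 with >=10 flagging clinically relevant
depressive symptoms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ItemSpec",
    "CesdResult",
    "CANONICAL_ITEMS",
    "PURPOSE_LABELS",
    "items_table",
    "score_cesd",
    "encode_purposes",
    "CESD_CUTOFF",
]

CESD_CUTOFF = 10

ORDINAL_0_3 = "ordinal_0_3"
BINARY = "binary"
DEPRESSIVE = "depressive"
INTERNET = "internet"


@dataclass(frozen=True)
class ItemSpec:
    """One measurement item / network node.

    Parameters
    ----------
    node_id : str
        Short label used everywhere (``De1``..``De10``, ``In1``..``In5``).
    name : str
        Human-readable item wording (wave-independent).
    item_type : str
        ``"ordinal_0_3"`` (CES-D, codes 0-3) or ``"binary"`` (purpose, 0/1).
    community : str
        ``"depressive"`` or ``"internet"``; the bipartition used by bridge
        expected influence.
    reverse_scored : bool
        True only for the two positively worded CES-D items.
    """

    node_id: str
    name: str
    item_type: str
    community: str
    reverse_scored: bool = False

    def __post_init__(self) -> None:
        if self.item_type not in (ORDINAL_0_3, BINARY):
            raise ValueError(f"unknown item_type {self.item_type!r}")
        if self.community not in (DEPRESSIVE, INTERNET):
            raise ValueError(f"unknown community {self.community!r}")
        if self.reverse_scored and self.item_type != ORDINAL_0_3:
            raise ValueError("reverse_scored requires an ordinal 0-3 item")

    @property
    def n_levels(self) -> int:
        return 4 if self.item_type == ORDINAL_0_3 else 2

    @property
    def max_code(self) -> int:
        return self.n_levels - 1


_DEPRESSIVE_NAMES = [
    "Unusually bothered",
    "Mind adrift",
    "Felt depressed",
    "Everything was an effort",
    "Felt hopeful about the future",
    "Felt fearful",
    "Restless sleep",
    "Lack of happiness",
    "Loneliness",
    "Inability get going",
]

PURPOSE_LABELS = [
    "Chatting",
    "Watching news",
    "Watching videos",
    "Playing games",
    "Financial management",
]

CANONICAL_ITEMS: tuple[ItemSpec, ...] = tuple(
    [
        ItemSpec(
            node_id=f"De{i + 1}",
            name=name,
            item_type=ORDINAL_0_3,
            community=DEPRESSIVE,
            reverse_scored=(i + 1) in (5, 8),
        )
        for i, name in enumerate(_DEPRESSIVE_NAMES)
    ]
    + [
        ItemSpec(
            node_id=f"In{i + 1}",
            name=name,
            item_type=BINARY,
            community=INTERNET,
        )
        for i, name in enumerate(PURPOSE_LABELS)
    ]
)


def items_table(items: Sequence[ItemSpec] = CANONICAL_ITEMS) -> pd.DataFrame:
    """Machine-readable item registry (one row per node, canonical order)."""
    return pd.DataFrame(
        {
            "node_id": [it.node_id for it in items],
            "name": [it.name for it in items],
            "item_type": [it.item_type for it in items],
            "community": [it.community for it in items],
            "reverse_scored": [it.reverse_scored for it in items],
        }
    )


@dataclass(frozen=True)
class CesdResult:
    """Scored CES-D questionnaire: total in 0-30, flag for total >= 10."""

    total_score: int
    above_cutoff: bool


def score_cesd(responses: Sequence[int]) -> CesdResult:
    """Score a complete 10-item CES-D response vector.

    Items 5 and 8 are reverse-scored (v -> 3 - v) before summation, so a
    respondent answering 0 ("rarely or none of the time") everywhere scores 6,
    not 0.

    Parameters
    ----------
    responses : sequence of 10 integers in {0, 1, 2, 3}
        Raw item codes in item order 1..10.

    Raises
    ------
    ValueError
        If the vector is not length 10 or any response is missing /
        out of range; the message names the offending item.
    """
    responses = list(responses)
    if len(responses) != 10:
        raise ValueError(f"expected 10 CES-D responses, got {len(responses)}")
    total = 0
    for idx, raw in enumerate(responses, start=1):
        if raw is None or raw != raw:  # None or NaN
            raise ValueError(f"CES-D item {idx}: response missing")
        if raw not in (0, 1, 2, 3):
            raise ValueError(f"CES-D item {idx}: response {raw!r} not in {{0,1,2,3}}")
        total += 3 - raw if idx in (5, 8) else raw
    return CesdResult(total_score=int(total), above_cutoff=total >= CESD_CUTOFF)


def encode_purposes(selected: Iterable[str]) -> tuple[int, ...]:
    """Indicator-code a set of endorsed Internet-use purposes.

    Returns a 5-tuple of 0/1 in canonical In1..In5 order; an endorsed purpose
    is coded 1, anything not selected is 0.

    Raises
    ------
    ValueError
        If a selection is not one of the five canonical labels.
    """
    chosen = set(selected)
    unknown = chosen - set(PURPOSE_LABELS)
    if unknown:
        raise ValueError(f"unknown purpose label(s): {sorted(unknown)!r}")
    return tuple(int(label in chosen) for label in PURPOSE_LABELS)
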