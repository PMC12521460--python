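"""Scoring of the three self-report scales and the dominant session emotion.

Each session's questionnaire comprises Foreign Language Enjoyment (FLE, 9
items), Foreign Language Classroom Boredom (FLCB, 8 items) and the short
Foreign Language Classroom Anxiety scale (FLCA, 8 items, two of which are
low-anxiety statements and therefore reverse-coded), all on a 5-point
Likert scale.  A scale score is the arithmetic mean of its (reverse-coded
where applicable) items; the dominant emotion is the label of the highest
score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Sequence

from .core import SessionKey

SCALE_ITEMS: Dict[str, int] = {"FLE": 9, "FLCB": 8, "FLCA": 8}
SCALE_EMOTION: Dict[str, str] = {"FLE": "enjoyment", "FLCB": "boredom", "FLCA": "anxiety"}

# The anxiety short form contains two low-anxiety statements; their exact
# positions depend on the administered form, so they are overridable per
# response.
DEFAULT_REVERSE_ITEMS: Dict[str, FrozenSet[int]] = {
    "FLE": frozenset(),
    "FLCB": frozenset(),
    "FLCA": frozenset({0, 1}),
}


@dataclass
class QuestionnaireResponse:
    key: SessionKey
    scale: str
    values: Sequence[int]
    reverse_items: FrozenSet[int] | None = None

    def __post_init__(self) -> None:
        if self.scale not in SCALE_ITEMS:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {sorted(SCALE_ITEMS)}")
        expected = SCALE_ITEMS[self.scale]
        if len(self.values) != expected:
            raise ValueError(f"{self.scale} requires {expected} items, got {len(self.values)}")
        for i, v in enumerate(self.values):
            if int(v) != v or not 1 <= int(v) <= 5:
                raise ValueError(f"{self.scale} item {i}: value {v!r} outside the 1-5 Likert range")
        if self.reverse_items is None:
            self.reverse_items = DEFAULT_REVERSE_ITEMS[self.scale]
        self.reverse_items = frozenset(int(i) for i in self.reverse_items)
        bad = [i for i in self.reverse_items if not 0 <= i < expected]
        if bad:
            raise ValueError(f"reverse item index out of range: {bad}")


def reverse_code(value: int) -> int:
    """Map a 5-point Likert value v to 6 - v (twice is the identity)."""
    return 6 - int(value)


def score_scale(resp: QuestionnaireResponse) -> float:
    """Mean of the (reverse-coded where flagged) items, to 3 decimals."""
    coded = [
        reverse_code(v) if i in resp.reverse_items else int(v)
        for i, v in enumerate(resp.values)
    ]
    return round(sum(coded) / len(coded), 3)


@dataclass
class SessionScores:
    key: SessionKey
    fle: float
    flcb: float
    flca: float

    @property
    def dominant(self) -> str:
        return dominant_emotion(self.fle, self.flcb, self.flca)


def dominant_emotion(fle: float, flcb: float, flca: float) -> str:
    """Label of the highest scale score; exact ties yield 'mixed'."""
    scores = {"enjoyment": fle, "boredom": flcb, "anxiety": flca}
    top = max(scores.values())
    winners = [k for k, v in scores.items() if v == top]
    return winners[0] if len(winners) == 1 else "mixed"


def score_session(responses: Sequence[QuestionnaireResponse]) -> SessionScores:
    """Score the three scales of one session's questionnaire."""
    keys = {r.key for r in responses}
    if len(keys) != 1:
        raise ValueError("responses must share one session key")
    by_scale = {r.scale: r for r in responses}
    missing = set(SCALE_ITEMS) - set(by_scale)
    if missing:
        raise ValueError(f"missing scales: {sorted(missing)}")
    return SessionScores(
        key=keys.pop(),
        fle=score_scale(by_scale["FLE"]),
        flcb=score_scale(by_scale["FLCB"]),
        flca=score_scale(by_scale["FLCA"]),
    )
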