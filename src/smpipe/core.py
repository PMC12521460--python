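"""Shared domain types: session identity and specific-moment event sets."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, List, Tuple

from .intervals import Interval, merge_intervals

MODALITIES = ("HR", "EFE", "FUSED")


@dataclass(frozen=True)
class SessionKey:
    """Identifies one student's session; times are seconds from session start."""

    student_id: str
    session_id: str
    session_start: float = 0.0


@dataclass
class SMEventSet:
    """Disjoint sorted half-open intervals flagged as specific moments.

    ``source_T`` records which window lengths (seconds) contributed; only
    meaningful for the HR modality.
    """

    key: SessionKey
    modality: str
    intervals: List[Interval] = field(default_factory=list)
    source_T: FrozenSet[int] = frozenset()

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        self.intervals = merge_intervals(self.intervals) if self.intervals else []
        self.source_T = frozenset(int(t) for t in self.source_T)

    def span(self) -> Tuple[float, float]:
        if not self.intervals:
            return (0.0, 0.0)
        return (self.intervals[0][0], self.intervals[-1][1])
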