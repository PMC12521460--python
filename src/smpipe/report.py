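"""Convergence of detected specific moments with classroom observations.

An SM interval "converges" with the observation track when it overlaps a
salient observed event by at least a minimum duration; the convergence rate
is the fraction of SM intervals so matched.  C1 denotes the heart-rate
branch, C2 the facial-expression branch; the fused decision is compared to
both, and the mean improvement summarises the multimodal gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .config import PipelineConfig
from .core import SessionKey, SMEventSet
from .intervals import overlap_length


@dataclass
class ObsEvent:
    start_s: float
    end_s: float
    label: str
    salient: bool = True

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError(f"observation event end must exceed start: [{self.start_s}, {self.end_s})")
        if not self.label:
            raise ValueError("observation event label must be nonempty")


@dataclass
class ObservationTrack:
    key: SessionKey
    events: List[ObsEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.start_s, e.end_s))

    def salient_intervals(self) -> List[tuple]:
        return [(e.start_s, e.end_s) for e in self.events if e.salient]


def convergence_rate(
    sms: SMEventSet,
    obs: ObservationTrack,
    min_overlap_s: float = 1.0,
    denominator: str = "sm",
) -> float:
    """Percentage convergence between an SM set and the observation track.

    With ``denominator='sm'`` (default): the fraction of SM intervals that
    overlap at least one salient event by >= ``min_overlap_s`` seconds —
    "X out of the N specific moments correspond to an observed event".
    With ``denominator='obs'``: the fraction of salient observed events
    covered by at least one SM interval; this event-coverage reading is
    monotone in the SM set, so a fused (union) decision can only match it
    or improve on it.  Defined as 0 when the denominator set is empty.
    """
    if sms.key != obs.key:
        raise ValueError("SM set and observation track belong to different sessions")
    return _pooled_rate([sms], [obs], min_overlap_s, denominator)


def _pooled_rate(
    sms_list: Sequence[SMEventSet],
    obs_list: Sequence[ObservationTrack],
    min_overlap_s: float,
    denominator: str = "sm",
) -> float:
    if denominator not in ("sm", "obs"):
        raise ValueError("denominator must be 'sm' or 'obs'")
    obs_by_key = {o.key: o for o in obs_list}
    sms_by_key: Dict = {}
    for s in sms_list:
        sms_by_key.setdefault(s.key, []).extend(s.intervals)
    total = matched = 0
    if denominator == "sm":
        for sms in sms_list:
            salient = obs_by_key[sms.key].salient_intervals() if sms.key in obs_by_key else []
            for iv in sms.intervals:
                total += 1
                if any(overlap_length(iv, ev) >= min_overlap_s for ev in salient):
                    matched += 1
    else:
        for key, obs in obs_by_key.items():
            ivs = sms_by_key.get(key, [])
            for ev in obs.salient_intervals():
                total += 1
                if any(overlap_length(iv, ev) >= min_overlap_s for iv in ivs):
                    matched += 1
    return 100.0 * matched / total if total else 0.0


def improvement_summary(c1: float, c2: float, fusion: float) -> float:
    """Mean gain of the fused convergence over the two unimodal ones, in percent.

    Reported to 2 decimals with half-up decimal rounding so that printed
    percentages reproduce exactly, e.g. (70, 55, 80) -> 17.5 and
    (54.54, 16.67, 63.62) -> 28.02.
    """
    from decimal import ROUND_HALF_UP, Decimal

    for v in (c1, c2, fusion):
        if not 0.0 <= v <= 100.0:
            raise ValueError("convergence rates must lie in [0, 100]")
    dc1, dc2, dfu = (Decimal(repr(float(v))) for v in (c1, c2, fusion))
    mean = ((dfu - dc1) + (dfu - dc2)) / 2
    return float(mean.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class SessionConvergence:
    session_id: str
    c1_obs: float
    c2_obs: float
    fusion_obs: float


@dataclass
class ConvergenceReport:
    """Per-student convergence summary.

    ``c1_obs``/``c2_obs``/``fusion_obs`` use the SM-count denominator;
    the ``*_event_coverage`` triple uses the salient-event denominator
    (fraction of observed salient events captured by each SM set).
    """

    student_id: str
    c1_obs: float
    c2_obs: float
    fusion_obs: float
    mean_improvement: float
    c1_event_coverage: float = 0.0
    c2_event_coverage: float = 0.0
    fusion_event_coverage: float = 0.0
    iou_percent: Optional[float] = None
    sessions: List[SessionConvergence] = field(default_factory=list)

    def as_dict(self) -> Dict:
        d = {
            "student": self.student_id,
            "c1_obs": self.c1_obs,
            "c2_obs": self.c2_obs,
            "fusion_obs": self.fusion_obs,
            "mean_improvement": self.mean_improvement,
            "c1_event_coverage": self.c1_event_coverage,
            "c2_event_coverage": self.c2_event_coverage,
            "fusion_event_coverage": self.fusion_event_coverage,
            "sessions": [vars(s) for s in self.sessions],
        }
        if self.iou_percent is not None:
            d["iou_percent"] = self.iou_percent
        return d


def build_report(
    hr_sms: Sequence[SMEventSet],
    efe_sms: Sequence[SMEventSet],
    fused: Sequence[SMEventSet],
    obs: Sequence[ObservationTrack],
    config: PipelineConfig,
    iou_percent: Optional[float] = None,
    aggregate: str = "pool",
) -> ConvergenceReport:
    """Assemble per-student convergence rates and the improvement summary.

    ``aggregate='pool'`` pools SM intervals over sessions before computing
    each rate; ``'mean'`` averages per-session rates instead.
    """
    students = {s.key.student_id for s in list(hr_sms) + list(efe_sms) + list(fused)}
    if len(students) > 1:
        raise ValueError("build_report covers a single student")
    student = students.pop() if students else ""
    mo = config.obs_match_min_overlap_s

    keys = sorted(
        {s.key for s in list(hr_sms) + list(efe_sms) + list(fused)},
        key=lambda k: (k.student_id, k.session_id),
    )
    by_key = lambda seq: {s.key: s for s in seq}
    hr_d, efe_d, fu_d, obs_d = by_key(hr_sms), by_key(efe_sms), by_key(fused), {o.key: o for o in obs}

    sessions = []
    for k in keys:
        empty_obs = ObservationTrack(key=k)
        o = obs_d.get(k, empty_obs)
        sessions.append(
            SessionConvergence(
                session_id=k.session_id,
                c1_obs=convergence_rate(hr_d[k], o, mo) if k in hr_d else 0.0,
                c2_obs=convergence_rate(efe_d[k], o, mo) if k in efe_d else 0.0,
                fusion_obs=convergence_rate(fu_d[k], o, mo) if k in fu_d else 0.0,
            )
        )

    if aggregate == "pool":
        c1 = _pooled_rate(list(hr_sms), list(obs), mo)
        c2 = _pooled_rate(list(efe_sms), list(obs), mo)
        fu = _pooled_rate(list(fused), list(obs), mo)
    elif aggregate == "mean":
        n = max(len(sessions), 1)
        c1 = sum(s.c1_obs for s in sessions) / n
        c2 = sum(s.c2_obs for s in sessions) / n
        fu = sum(s.fusion_obs for s in sessions) / n
    else:
        raise ValueError("aggregate must be 'pool' or 'mean'")

    return ConvergenceReport(
        student_id=student,
        c1_obs=c1,
        c2_obs=c2,
        fusion_obs=fu,
        mean_improvement=improvement_summary(c1, c2, fu),
        c1_event_coverage=_pooled_rate(list(hr_sms), list(obs), mo, "obs"),
        c2_event_coverage=_pooled_rate(list(efe_sms), list(obs), mo, "obs"),
        fusion_event_coverage=_pooled_rate(list(fused), list(obs), mo, "obs"),
        iou_percent=iou_percent,
        sessions=sessions,
    )
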