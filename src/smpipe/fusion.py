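"""Decision-level fusion of the two modalities and temporal IoU.

Both branches emit binary specific-moment decisions over time.  They are
aligned on a common tick grid (default 1 s) and fused with a weighted
per-tick vote in which heart rate carries at least as much weight as facial
expression; outside the HR recording coverage the facial stream is the sole
source and decides alone.  Temporal IoU between the two unimodal event sets
quantifies their agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .config import PipelineConfig
from .core import SMEventSet
from .intervals import Interval, intersect, merge_intervals


@dataclass
class TimelineMask:
    """Boolean occupancy per tick of width ``resolution`` from ``start``.

    Tick t covers [start + t*res, start + (t+1)*res); it is marked when that
    span intersects any source interval.
    """

    resolution: float
    start: float
    ticks: np.ndarray

    @property
    def end(self) -> float:
        return self.start + len(self.ticks) * self.resolution

    @classmethod
    def rasterize(
        cls, intervals: Sequence[Interval], start: float, end: float, resolution: float
    ) -> "TimelineMask":
        n = max(0, int(math.ceil((end - start) / resolution - 1e-9)))
        ticks = np.zeros(n, dtype=bool)
        for s, e in intervals:
            lo = int(math.floor((s - start) / resolution + 1e-9))
            hi = int(math.ceil((e - start) / resolution - 1e-9))
            lo, hi = max(lo, 0), min(hi, n)
            if hi > lo:
                ticks[lo:hi] = True
        return cls(resolution=resolution, start=start, ticks=ticks)

    def to_intervals(self) -> List[Interval]:
        out: List[Interval] = []
        t = self.ticks
        if t.size == 0:
            return out
        edges = np.flatnonzero(np.diff(np.concatenate(([0], t.view(np.int8), [0]))))
        for lo, hi in zip(edges[::2], edges[1::2]):
            out.append((self.start + lo * self.resolution, self.start + hi * self.resolution))
        return out


def _common_span(*interval_sets: Sequence[Interval]) -> tuple[float, float]:
    pts = [p for ivs in interval_sets for iv in ivs for p in iv]
    if not pts:
        return (0.0, 0.0)
    return (min(pts), max(pts))


def restrict_to_coverage(efe_sms: SMEventSet, hr_coverage: Sequence[Interval]) -> SMEventSet:
    """Clip facial-expression SMs to the periods with HR recording."""
    return SMEventSet(
        key=efe_sms.key,
        modality=efe_sms.modality,
        intervals=intersect(efe_sms.intervals, merge_intervals(hr_coverage) if hr_coverage else []),
    )


def temporal_iou(a: SMEventSet, b: SMEventSet, resolution: float = 1.0) -> float:
    """Intersection-over-union of two event sets on a common tick grid, in percent.

    Defined as 0 when the union is empty.
    """
    start, end = _common_span(a.intervals, b.intervals)
    if end <= start:
        return 0.0
    ma = TimelineMask.rasterize(a.intervals, start, end, resolution).ticks
    mb = TimelineMask.rasterize(b.intervals, start, end, resolution).ticks
    union = np.logical_or(ma, mb).sum()
    if union == 0:
        return 0.0
    inter = np.logical_and(ma, mb).sum()
    return 100.0 * float(inter) / float(union)


def fuse_decisions(
    hr_sms: SMEventSet,
    efe_sms: SMEventSet,
    hr_coverage: Sequence[Interval],
    config: PipelineConfig,
) -> SMEventSet:
    """Weighted per-tick vote with heart-rate precedence.

    Within HR coverage the tick score is w_hr*[HR-SM] + w_efe*[EFE-SM];
    outside coverage facial expression is the sole source and an EFE-SM
    tick scores 1.  Ticks with score >= fusion_threshold form the fused
    set.  The default weights (0.7, 0.3) and threshold 0.3 make the fused
    set the union of the modalities within coverage.
    """
    w_hr, w_efe = config.fusion_weights
    res = float(config.iou_resolution_s)
    cov = merge_intervals(hr_coverage) if hr_coverage else []
    start, end = _common_span(hr_sms.intervals, efe_sms.intervals, cov)
    if end <= start:
        return SMEventSet(key=hr_sms.key, modality="FUSED", intervals=[])
    m_hr = TimelineMask.rasterize(hr_sms.intervals, start, end, res).ticks
    m_efe = TimelineMask.rasterize(efe_sms.intervals, start, end, res).ticks
    m_cov = TimelineMask.rasterize(cov, start, end, res).ticks
    score = np.where(
        m_cov,
        w_hr * m_hr + w_efe * m_efe,
        m_efe.astype(float),
    )
    fused = TimelineMask(resolution=res, start=start, ticks=score >= config.fusion_threshold - 1e-12)
    return SMEventSet(key=hr_sms.key, modality="FUSED", intervals=fused.to_intervals())
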