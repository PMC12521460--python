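"""Heart-rate series, sliding-window segmentation, and the 6-feature summary.

Each window of bpm samples is summarised by six statistics of the HR
dynamics: the mean and standard deviation of the samples, the mean absolute
first difference (speed), the mean absolute second difference
(acceleration), and the two speed/acceleration values normalised by the
window standard deviation.  Windows of length T are laid out with a
configurable overlap inside each contiguous recording-coverage interval and
never straddle coverage gaps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import SessionKey
from .intervals import Interval

logger = logging.getLogger(__name__)

BPM_MIN, BPM_MAX = 30.0, 220.0

FEATURE_NAMES = ("mu", "sigma", "mu_v", "mu_v_norm", "mu_a", "mu_a_norm")


@dataclass
class HRSeries:
    """A timestamped bpm trace with explicit recording-coverage intervals.

    ``mask`` marks physiologically plausible samples; implausible bpm values
    stay in the arrays (so lengths are preserved) but are excluded from
    coverage and features.
    """

    key: SessionKey
    times: np.ndarray
    bpm: np.ndarray
    mask: np.ndarray
    coverage: List[Interval] = field(default_factory=list)

    @classmethod
    def from_samples(
        cls,
        key: SessionKey,
        times: Sequence[float],
        bpm: Sequence[float],
        nominal_rate_hz: float = 1.0,
    ) -> "HRSeries":
        """Build a series, masking out-of-range bpm and computing coverage.

        Coverage intervals are maximal runs of valid samples whose
        inter-sample gap never exceeds twice the nominal period; a sample at
        time t contributes [t, t + period) to its interval.
        """
        times = np.asarray(times, dtype=float)
        bpm = np.asarray(bpm, dtype=float)
        if times.size != bpm.size:
            raise ValueError("times and bpm must have equal length")
        if times.size == 0:
            raise ValueError("empty heart-rate series")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        mask = (bpm >= BPM_MIN) & (bpm <= BPM_MAX) & np.isfinite(bpm)
        n_bad = int((~mask).sum())
        if n_bad:
            warnings.warn(
                f"{key.student_id}/{key.session_id}: masked {n_bad} bpm sample(s) "
                f"outside [{BPM_MIN:g}, {BPM_MAX:g}]",
                stacklevel=2,
            )
        period = 1.0 / nominal_rate_hz
        coverage = _coverage_from_samples(times[mask], max_gap=2.0 * period, period=period)
        return cls(key=key, times=times, bpm=bpm, mask=mask, coverage=coverage)

    def valid_times(self) -> np.ndarray:
        return self.times[self.mask]

    def valid_bpm(self) -> np.ndarray:
        return self.bpm[self.mask]


def _coverage_from_samples(times: np.ndarray, max_gap: float, period: float) -> List[Interval]:
    if times.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(times) > max_gap)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [times.size - 1]))
    return [(float(times[i]), float(times[j] + period)) for i, j in zip(starts, ends)]


@dataclass
class HRWindow:
    """One analysis window [start_s, end_s) with its bpm samples."""

    start_s: float
    end_s: float
    values: np.ndarray

    @property
    def T(self) -> float:
        return self.end_s - self.start_s


@dataclass
class HRFeatureVector:
    mu: float
    sigma: float
    mu_v: float
    mu_v_norm: float
    mu_a: float
    mu_a_norm: float

    def as_array(self) -> np.ndarray:
        return np.array([self.mu, self.sigma, self.mu_v, self.mu_v_norm, self.mu_a, self.mu_a_norm])


def segment_windows(series: HRSeries, T: float, overlap: float) -> List[HRWindow]:
    """Slide windows of length T with the given overlap inside each coverage interval.

    Window starts within coverage [c0, c1) are c0, c0 + (1-overlap)T, ... as
    long as start + T <= c1; an interval shorter than T yields no windows.
    """
    if not 0.0 < overlap < 1.0:
        raise ValueError("overlap must lie strictly between 0 and 1")
    step = (1.0 - overlap) * T
    vt = series.valid_times()
    vb = series.valid_bpm()
    out: List[HRWindow] = []
    for c0, c1 in series.coverage:
        # small epsilon guards float error in the start arithmetic
        n_starts = int(np.floor((c1 - c0 - T) / step + 1e-9)) + 1 if c1 - c0 >= T else 0
        for k in range(n_starts):
            s = c0 + k * step
            e = s + T
            sel = (vt >= s) & (vt < e)
            vals = vb[sel]
            if vals.size >= 2:
                out.append(HRWindow(start_s=s, end_s=e, values=vals))
    return out


def extract_hr_features(window: HRWindow) -> HRFeatureVector:
    """Compute the 6-dimensional dynamics summary of a window.

    Uses the population standard deviation; normalised speed/acceleration
    are defined as 0 when sigma is 0 (a flat window has no dynamics).
    Differences are taken over sample index.
    """
    x = np.asarray(window.values, dtype=float)
    if x.size < 3:
        raise ValueError("window needs at least 3 samples for second differences")
    mu = float(np.mean(x))
    sigma = float(np.std(x))
    mu_v = float(np.mean(np.abs(np.diff(x))))
    mu_a = float(np.mean(np.abs(np.diff(x, n=2))))
    if sigma > 0.0:
        mu_v_norm = mu_v / sigma
        mu_a_norm = mu_a / sigma
    else:
        mu_v_norm = mu_a_norm = 0.0
    return HRFeatureVector(mu, sigma, mu_v, mu_v_norm, mu_a, mu_a_norm)


def feature_matrix(windows: Sequence[HRWindow]) -> np.ndarray:
    """Stack per-window feature vectors into an (n_windows, 6) matrix."""
    if not windows:
        return np.empty((0, len(FEATURE_NAMES)))
    return np.vstack([extract_hr_features(w).as_array() for w in windows])
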