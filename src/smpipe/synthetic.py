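"""Synthetic multimodal classroom sessions with known ground truth.

A session consists of a per-student baseline heart-rate trace with AR(1)
noise, into which a handful of arousal episodes are injected by scaling the
innovation magnitude — raising the mean absolute speed and acceleration of
the signal, the features that drive specific-moment separation — together
with a neutral-dominant facial-expression stream whose episode frames shift
probability mass toward a non-neutral class, an observation track whose
salient events partially overlap the episodes, and Likert questionnaire
responses whose means move with the session's episode valence.

One master seed streams per-session sub-seeds through
``numpy.random.SeedSequence``, so cohorts are reproducible and individual
sessions regenerable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import SessionKey, SMEventSet
from .efe import EMOTION_CLASSES, EFEFrameSeries
from .hr import BPM_MAX, BPM_MIN, HRSeries
from .intervals import overlap_length
from .questionnaires import (
    DEFAULT_REVERSE_ITEMS,
    SCALE_ITEMS,
    QuestionnaireResponse,
    reverse_code,
)
from .report import ObsEvent, ObservationTrack

logger = logging.getLogger(__name__)

NEUTRAL = EMOTION_CLASSES.index("neutral")


@dataclass
class SyntheticConfig:
    """Generation parameters; the defaults define the study conditions."""

    n_students: int = 3
    n_sessions: int = 2
    session_length_s: int = 4800  # ~80 min
    hr_baseline_range_bpm: Tuple[float, float] = (60.0, 90.0)
    ar1_coef: float = 0.9
    noise_sd_bpm: float = 1.5
    episodes_per_session: int = 5
    episode_length_s: int = 120
    episode_dynamics_multiplier: float = 3.0
    # a confident pretrained recogniser on a mostly-neutral face: mean
    # neutral probability 0.8 with modest per-frame spread
    efe_dirichlet_base: Tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 24.0)
    efe_episode_shift: float = 0.5
    efe_quality_dropout: float = 0.02
    obs_overlap_prob: float = 0.8
    obs_false_event_rate: float = 2.0  # expected non-salient events per session
    questionnaire_effect: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("efe_episode_shift", "efe_quality_dropout", "obs_overlap_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.ar1_coef < 1.0:
            raise ValueError("ar1_coef must lie in [0, 1)")
        if self.episode_dynamics_multiplier < 1.0:
            raise ValueError("episode_dynamics_multiplier must be >= 1")
        for name in ("session_length_s", "episode_length_s", "episodes_per_session",
                     "n_students", "n_sessions"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.episodes_per_session * self.episode_length_s > self.session_length_s:
            raise ValueError("episodes do not fit in the session")


@dataclass
class SessionBundle:
    key: SessionKey
    hr: HRSeries
    efe: EFEFrameSeries
    obs: ObservationTrack
    truth: SMEventSet
    questionnaire: List[QuestionnaireResponse]
    baseline_bpm: float


def _place_episodes(cfg: SyntheticConfig, rng: np.random.Generator) -> List[Tuple[float, float]]:
    """Non-overlapping episodes: one per equal slot, jittered within it."""
    L, n, ep = cfg.session_length_s, cfg.episodes_per_session, cfg.episode_length_s
    slot = L / n
    out = []
    for k in range(n):
        lo = k * slot
        hi = (k + 1) * slot - ep
        start = float(np.floor(rng.uniform(lo, max(hi, lo + 1e-9))))
        out.append((start, start + ep))
    return out


def _hr_trace(
    cfg: SyntheticConfig,
    baseline: float,
    episodes: Sequence[Tuple[float, float]],
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    n = cfg.session_length_s  # 1 Hz
    t = np.arange(n, dtype=float)
    phi = cfg.ar1_coef
    innov_sd = cfg.noise_sd_bpm * np.sqrt(1.0 - phi**2)
    scale = np.full(n, innov_sd)
    for s, e in episodes:
        scale[(t >= s) & (t < e)] *= cfg.episode_dynamics_multiplier
    eps = rng.normal(0.0, 1.0, size=n) * scale
    x = np.empty(n)
    x[0] = rng.normal(0.0, cfg.noise_sd_bpm)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i]
    bpm = baseline + x
    n_clip = int(np.sum((bpm < BPM_MIN) | (bpm > BPM_MAX)))
    if n_clip:
        logger.info("clipped %d synthetic bpm sample(s) to [%g, %g]", n_clip, BPM_MIN, BPM_MAX)
    return t, np.clip(bpm, BPM_MIN, BPM_MAX)


def _efe_stream(
    cfg: SyntheticConfig,
    episodes: Sequence[Tuple[float, float]],
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, List[int]]:
    n = cfg.session_length_s  # 1 fps
    t = np.arange(n, dtype=float)
    feats = rng.dirichlet(np.asarray(cfg.efe_dirichlet_base, dtype=float), size=n)
    non_neutral = [i for i in range(len(cfg.efe_dirichlet_base)) if i != NEUTRAL]
    targets: List[int] = []
    for s, e in episodes:
        c = int(rng.choice(non_neutral))
        targets.append(c)
        sel = (t >= s) & (t < e)
        onehot = np.zeros(feats.shape[1])
        onehot[c] = 1.0
        feats[sel] = (1.0 - cfg.efe_episode_shift) * feats[sel] + cfg.efe_episode_shift * onehot
    mask = rng.random(n) >= cfg.efe_quality_dropout
    return t, feats, mask, targets


def _obs_track(
    cfg: SyntheticConfig,
    key: SessionKey,
    episodes: Sequence[Tuple[float, float]],
    rng: np.random.Generator,
) -> ObservationTrack:
    events: List[ObsEvent] = []
    for i, (s, e) in enumerate(episodes):
        if rng.random() < cfg.obs_overlap_prob:
            # salient note partially overlapping the episode
            start = float(np.floor(rng.uniform(s - 30.0, s + (e - s) / 2.0)))
            dur = float(np.floor(rng.uniform(30.0, e - s)))
            start = max(0.0, start)
            end = min(float(cfg.session_length_s), start + dur)
            if end > start:
                events.append(ObsEvent(start, end, label=f"salient_{i}", salient=True))
    n_false = int(rng.poisson(cfg.obs_false_event_rate))
    for j in range(n_false):
        start = float(np.floor(rng.uniform(0, cfg.session_length_s - 60)))
        dur = float(np.floor(rng.uniform(20, 90)))
        events.append(ObsEvent(start, min(start + dur, float(cfg.session_length_s)),
                               label=f"routine_{j}", salient=False))
    return ObservationTrack(key=key, events=events)


def _questionnaire(
    cfg: SyntheticConfig,
    key: SessionKey,
    valence: float,
    rng: np.random.Generator,
) -> List[QuestionnaireResponse]:
    means = {
        "FLE": 3.5 + cfg.questionnaire_effect * valence,
        "FLCB": 2.5 - 0.3 * valence,
        "FLCA": 2.2 - cfg.questionnaire_effect * valence,
    }
    out = []
    for scale, n_items in SCALE_ITEMS.items():
        latent = np.clip(np.rint(rng.normal(means[scale], 0.8, size=n_items)), 1, 5).astype(int)
        values = [
            reverse_code(v) if i in DEFAULT_REVERSE_ITEMS[scale] else int(v)
            for i, v in enumerate(latent)
        ]
        out.append(QuestionnaireResponse(key=key, scale=scale, values=values))
    return out


def generate_session(
    cfg: SyntheticConfig,
    key: SessionKey,
    seed: int,
    baseline_bpm: Optional[float] = None,
) -> SessionBundle:
    """Generate one session deterministically from its seed."""
    rng = np.random.default_rng(seed)
    if baseline_bpm is None:
        baseline_bpm = float(rng.uniform(*cfg.hr_baseline_range_bpm))
    episodes = _place_episodes(cfg, rng)
    t_hr, bpm = _hr_trace(cfg, baseline_bpm, episodes, rng)
    t_efe, feats, qmask, targets = _efe_stream(cfg, episodes, rng)
    obs = _obs_track(cfg, key, episodes, rng)
    valence = float(np.mean([1.0 if c == EMOTION_CLASSES.index("happy") else -0.5 for c in targets]))
    questionnaire = _questionnaire(cfg, key, valence, rng)
    hr = HRSeries.from_samples(key, t_hr, bpm)
    efe = EFEFrameSeries(key=key, frame_times=t_efe, features=feats, quality_mask=qmask)
    truth = SMEventSet(key=key, modality="HR", intervals=list(episodes))
    return SessionBundle(
        key=key, hr=hr, efe=efe, obs=obs, truth=truth,
        questionnaire=questionnaire, baseline_bpm=baseline_bpm,
    )


def generate_cohort(cfg: SyntheticConfig) -> List[SessionBundle]:
    """Generate n_students x n_sessions bundles from the master seed."""
    ss = np.random.SeedSequence(cfg.seed)
    student_seqs = ss.spawn(cfg.n_students)
    bundles: List[SessionBundle] = []
    for i, sseq in enumerate(student_seqs):
        baseline_rng = np.random.default_rng(sseq.spawn(1)[0])
        baseline = float(baseline_rng.uniform(*cfg.hr_baseline_range_bpm))
        for j, sess_seq in enumerate(sseq.spawn(cfg.n_sessions)):
            key = SessionKey(student_id=f"S{i + 1}", session_id=f"sess{j + 1:02d}")
            seed = int(sess_seq.generate_state(1)[0] % (2**31))
            bundles.append(generate_session(cfg, key, seed, baseline_bpm=baseline))
    return bundles


# ---------------------------------------------------------------------------
# Detection evaluation against ground truth

@dataclass
class DetectionEval:
    precision: float
    recall: float
    f1: float
    n_detected: int
    n_truth: int
    n_matched: int


def evaluate_detection(
    detected: SMEventSet, truth: SMEventSet, min_overlap_s: float = 1.0
) -> DetectionEval:
    """Interval-level precision/recall with greedy one-to-one matching.

    Candidate pairs with overlap >= ``min_overlap_s`` are matched greedily
    by decreasing overlap length; each truth and each detected interval is
    used at most once.
    """
    pairs = []
    for di, d in enumerate(detected.intervals):
        for ti, tr in enumerate(truth.intervals):
            ov = overlap_length(d, tr)
            if ov >= min_overlap_s:
                pairs.append((ov, di, ti))
    pairs.sort(key=lambda p: -p[0])
    used_d, used_t = set(), set()
    for _, di, ti in pairs:
        if di not in used_d and ti not in used_t:
            used_d.add(di)
            used_t.add(ti)
    nm = len(used_t)
    nd, nt = len(detected.intervals), len(truth.intervals)
    precision = nm / nd if nd else 0.0
    recall = nm / nt if nt else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return DetectionEval(precision, recall, f1, nd, nt, nm)
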