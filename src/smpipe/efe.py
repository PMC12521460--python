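"""Emotional facial-expression frame streams and the pluggable backend contract.

The pipeline consumes per-frame d-dimensional emotion features (default
d=7 class probabilities in the order angry, disgust, fear, happy, sad,
surprise, neutral) produced by some external recogniser.  No network is
implemented here; any object satisfying :class:`EmotionBackend` can stand
behind the stream, and tests/synthetic data bypass images entirely.
"""

from __future__ import annotations

import abc
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .core import SessionKey

EMOTION_CLASSES = ("angry", "disgust", "fear", "happy", "sad", "surprise", "neutral")


@dataclass
class EFEFrameSeries:
    """Per-frame emotion feature vectors with a per-frame quality mask.

    Low-quality (occluded, undetected-face) frames carry ``quality_mask``
    False and are excluded from clustering and the dominant-expression vote.
    """

    key: SessionKey
    frame_times: np.ndarray
    features: np.ndarray  # (n_frames, d)
    quality_mask: np.ndarray
    fps: float = 1.0
    class_names: Sequence[str] = EMOTION_CLASSES

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.quality_mask = np.asarray(self.quality_mask, dtype=bool)
        if len(self.frame_times) != len(self.features):
            raise ValueError("frame_times and features must have equal length")
        if len(self.quality_mask) != len(self.frame_times):
            raise ValueError("quality_mask length mismatch")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def dim(self) -> int:
        return self.features.shape[1]

    def valid_features(self) -> np.ndarray:
        return self.features[self.quality_mask]

    def valid_times(self) -> np.ndarray:
        return self.frame_times[self.quality_mask]


def renormalize_rows(features: np.ndarray, atol: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    """Renormalise probability rows to sum to 1; flag all-zero rows as missing.

    Returns ``(normalised, valid_mask)``.  Rows already within ``atol`` of 1
    are untouched; others are rescaled with a warning.  Idempotent.
    """
    features = np.asarray(features, dtype=float)
    if np.any(features < -atol):
        raise ValueError("probability features must be nonnegative")
    sums = features.sum(axis=1)
    valid = sums > atol
    off = valid & (np.abs(sums - 1.0) > atol)
    if off.any():
        warnings.warn(f"renormalized {int(off.sum())} feature row(s) not summing to 1", stacklevel=2)
    out = features.copy()
    out[valid] = out[valid] / sums[valid, None]
    return out, valid


def downsample_frames(frame_times: Sequence[float], target_fps: float) -> np.ndarray:
    """Indices of the first frame in each 1/target_fps bucket.

    Reduces a native-rate stream (e.g. 25 fps) to the analysis rate
    (default 1 fps).  Output times are strictly increasing.
    """
    if target_fps <= 0:
        raise ValueError("target_fps must be positive")
    t = np.asarray(frame_times, dtype=float)
    if t.size == 0:
        return np.empty(0, dtype=int)
    buckets = np.floor(t * target_fps + 1e-9).astype(np.int64)
    _, first = np.unique(buckets, return_index=True)
    return np.sort(first)


def dominant_expression(series: EFEFrameSeries) -> int:
    """Most frequent argmax class over unmasked frames; ties -> lowest index."""
    feats = series.valid_features()
    if feats.shape[0] == 0:
        raise ValueError("no unmasked frames")
    per_frame = np.argmax(feats, axis=1)
    counts = np.bincount(per_frame, minlength=series.dim)
    return int(np.argmax(counts))  # argmax returns the lowest index on ties


class EmotionBackend(abc.ABC):
    """Contract for a facial-emotion feature extractor.

    Implementations must be deterministic for a fixed input image.  The
    pipeline itself never calls ``transform``; it exists so precomputed
    streams and future recognisers share one interface.
    """

    name: str = "abstract"
    dim: int = len(EMOTION_CLASSES)

    @abc.abstractmethod
    def transform(self, image: np.ndarray) -> np.ndarray:
        """Map a face image to a d-dimensional feature vector."""


_BACKENDS: Dict[str, EmotionBackend] = {}


def register_backend(backend: EmotionBackend) -> None:
    _BACKENDS[backend.name] = backend


def get_backend(name: str) -> EmotionBackend:
    try:
        return _BACKENDS[name]
    except KeyError:
        raise KeyError(f"no emotion backend registered under {name!r}") from None


class HistogramBackend(EmotionBackend):
    """Deterministic stand-in backend mapping an image to a 7-bin intensity histogram.

    Synthetic by construction; useful for exercising the backend registry
    without any trained recogniser.
    """

    name = "histogram"

    def transform(self, image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=float).ravel()
        hist, _ = np.histogram(img, bins=self.dim, range=(img.min(), img.max() + 1e-9))
        total = hist.sum()
        return hist / total if total else np.full(self.dim, 1.0 / self.dim)


register_backend(HistogramBackend())
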