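"""Unsupervised specific-moment detection.

A subject's feature vectors (per-window HR statistics, or per-frame emotion
vectors) are modelled as a two-component Gaussian mixture: the majority
component captures the subject's baseline, the minority component the
specific moments (SMs) — stretches whose dynamics deviate from that
baseline.  The estimator follows the scikit-learn fit/predict protocol so
it composes with pipelines and model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_array, check_is_fitted

from .config import PipelineConfig
from .core import SessionKey, SMEventSet
from .efe import EFEFrameSeries
from .hr import FEATURE_NAMES, HRSeries, HRWindow, feature_matrix, segment_windows
from .intervals import Interval, merge_intervals

MIN_ROWS = 10


def select_sm_cluster(
    weights: np.ndarray, means: np.ndarray, global_mean: np.ndarray, tie_margin: float = 0.05
) -> int:
    """Pick the component representing specific moments.

    The minority (smaller mixing weight) component is the outlier cluster.
    When the weights are within ``tie_margin`` of each other the component
    whose mean lies farther (Euclidean) from the global feature mean wins.
    """
    weights = np.asarray(weights, dtype=float)
    if abs(weights[0] - weights[1]) < tie_margin:
        d = np.linalg.norm(np.asarray(means) - np.asarray(global_mean), axis=1)
        return int(np.argmax(d))
    return int(np.argmin(weights))


class TwoClusterAnomalyDetector(BaseEstimator):
    """Two-component GMM anomaly detector with minority-cluster selection.

    Parameters
    ----------
    random_state : int
        Seed for the mixture fit; the best of ``n_init`` restarts by
        log-likelihood is kept, so results are deterministic given the seed.
    standardize : bool
        Z-score columns before fitting.  Recommended for the heterogeneous
        HR feature scales; off by default for probability vectors.
    tie_margin : float
        Mixing-weight margin below which the farther-from-centre component
        is chosen as the SM cluster instead of the minority one.

    Attributes
    ----------
    converged_ : bool
        False for degenerate input (all rows identical) or a non-converged
        EM run; downstream detection then yields an empty SM set.
    sm_component_ : int
        Index of the specific-moment component.
    weights_, means_, covariances_ : mixture parameters (original scale of
        the standardized space when ``standardize`` is on).
    """

    def __init__(
        self,
        random_state: int = 0,
        n_init: int = 5,
        max_iter: int = 200,
        tol: float = 1e-4,
        standardize: bool = True,
        tie_margin: float = 0.05,
    ):
        self.random_state = random_state
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.standardize = standardize
        self.tie_margin = tie_margin

    def fit(self, X: np.ndarray, y: None = None) -> "TwoClusterAnomalyDetector":
        X = check_array(X, ensure_min_samples=MIN_ROWS)
        if not np.all(np.isfinite(X)):
            raise ValueError("features contain non-finite entries")
        self.n_features_in_ = X.shape[1]
        self._mean = X.mean(axis=0)
        self._scale = X.std(axis=0)
        if np.allclose(X, X[0]):
            # all rows identical: no structure to separate
            self.converged_ = False
            self._gmm = None
            return self
        Z = self._transform(X)
        gmm = GaussianMixture(
            n_components=2,
            covariance_type="full",
            n_init=self.n_init,
            max_iter=self.max_iter,
            tol=self.tol,
            random_state=self.random_state,
            reg_covar=1e-6,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gmm.fit(Z)
        self._gmm = gmm
        self.converged_ = bool(gmm.converged_)
        self.weights_ = gmm.weights_
        self.means_ = gmm.means_
        self.covariances_ = gmm.covariances_
        self.sm_component_ = select_sm_cluster(
            gmm.weights_, gmm.means_, Z.mean(axis=0), self.tie_margin
        )
        return self

    def _transform(self, X: np.ndarray) -> np.ndarray:
        if not self.standardize:
            return X
        scale = np.where(self._scale > 0, self._scale, 1.0)
        return (X - self._mean) / scale

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Binary SM labels: 1 for specific-moment rows, 0 for baseline."""
        check_is_fitted(self, "converged_")
        X = check_array(X)
        if self._gmm is None or not self.converged_:
            return np.zeros(X.shape[0], dtype=int)
        comp = self._gmm.predict(self._transform(X))
        return (comp == self.sm_component_).astype(int)

    def fit_predict(self, X: np.ndarray, y: None = None) -> np.ndarray:
        return self.fit(X).predict(X)


def fit_two_cluster_gmm(features: np.ndarray, seed: int, **kwargs) -> TwoClusterAnomalyDetector:
    """Functional wrapper over :class:`TwoClusterAnomalyDetector`."""
    return TwoClusterAnomalyDetector(random_state=seed, **kwargs).fit(features)


# ---------------------------------------------------------------------------
# Silhouette (clustering cohesion/separation)

@dataclass
class SilhouetteResult:
    per_sample_scores: np.ndarray
    mean_score: float


def silhouette(features: np.ndarray, labels: Sequence[int]) -> SilhouetteResult:
    """Per-sample silhouette s(i) = (b(i) - a(i)) / max(a(i), b(i)).

    a(i) is the mean Euclidean distance from i to the other members of its
    cluster; b(i) the smallest mean distance to any other cluster.  Points
    in singleton clusters score 0, as do points with max(a, b) = 0
    (coincident clusters).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    uniq, inv = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    D = cdist(X, X)
    n = X.shape[0]
    sizes = np.bincount(inv)
    # sum of distances from each point to each cluster
    sums = np.zeros((n, uniq.size))
    for k in range(uniq.size):
        sums[:, k] = D[:, inv == k].sum(axis=1)
    own = inv
    s = np.zeros(n)
    for i in range(n):
        k = own[i]
        if sizes[k] == 1:
            continue  # singleton convention: 0
        a = sums[i, k] / (sizes[k] - 1)
        b = np.min([sums[i, m] / sizes[m] for m in range(uniq.size) if m != k])
        denom = max(a, b)
        s[i] = (b - a) / denom if denom > 0 else 0.0
    return SilhouetteResult(per_sample_scores=s, mean_score=float(np.mean(s)))


DEFAULT_FEATURE_SUBSETS: Dict[str, Tuple[str, ...]] = {
    **{name: (name,) for name in FEATURE_NAMES},
    "level (mu, sigma)": ("mu", "sigma"),
    "speed (mu_v, mu_v_norm)": ("mu_v", "mu_v_norm"),
    "acceleration (mu_a, mu_a_norm)": ("mu_a", "mu_a_norm"),
    "dynamics (all speed+acceleration)": ("mu_v", "mu_v_norm", "mu_a", "mu_a_norm"),
    "all": FEATURE_NAMES,
}


def feature_ablation_silhouettes(
    features: np.ndarray,
    labels: Sequence[int],
    feature_names: Sequence[str] = FEATURE_NAMES,
    subsets: Optional[Dict[str, Tuple[str, ...]]] = None,
) -> List[Tuple[str, float]]:
    """Mean silhouette restricted to each feature subset, best first.

    Ranks which features carry the cluster separation — with the default
    subsets, each of the six HR features alone plus the level, speed and
    acceleration groups.
    """
    X = np.asarray(features, dtype=float)
    names = list(feature_names)
    if len(names) != X.shape[1]:
        raise ValueError("feature_names length must match the feature dimension")
    # duplicate names get positional labels so ablation columns stay distinct
    seen: Dict[str, int] = {}
    uniq_names = []
    for n in names:
        seen[n] = seen.get(n, 0) + 1
        uniq_names.append(n if seen[n] == 1 else f"{n}#{seen[n]}")
    idx = {n: i for i, n in enumerate(uniq_names)}
    if subsets is None:
        subsets = {k: v for k, v in DEFAULT_FEATURE_SUBSETS.items() if set(v) <= set(uniq_names)}
        for n in uniq_names:
            subsets.setdefault(n, (n,))
    rows = []
    for label, cols in subsets.items():
        sub = X[:, [idx[c] for c in cols]]
        rows.append((label, silhouette(sub, labels).mean_score))
    rows.sort(key=lambda r: -r[1])
    return rows


# ---------------------------------------------------------------------------
# HR-branch detection

def _hr_windows_by_T(
    series_list: Sequence[HRSeries], T: float, overlap: float
) -> List[Tuple[SessionKey, HRWindow]]:
    out = []
    for s in series_list:
        for w in segment_windows(s, T, overlap):
            out.append((s.key, w))
    return out


def detect_sm_hr(
    series: HRSeries | Sequence[HRSeries],
    config: PipelineConfig,
    return_models: bool = False,
):
    """Detect heart-rate specific moments for one student.

    For each window length T in the grid the windows of all the student's
    sessions are pooled, featurized, clustered, and SM-labelled windows
    mapped back to their [start, start+T) interval; the final per-session
    event set is the merged union over the whole T grid.  Returns a mapping
    from session key to event set (empty sets for sessions with no SMs);
    with ``return_models`` also the fitted detector per window length.
    """
    series_list = [series] if isinstance(series, HRSeries) else list(series)
    if not series_list:
        return {}
    students = {s.key.student_id for s in series_list}
    if len(students) > 1:
        raise ValueError("detect_sm_hr pools sessions of a single student")
    per_session: Dict[SessionKey, List[Interval]] = {s.key: [] for s in series_list}
    source_T: Dict[SessionKey, set] = {s.key: set() for s in series_list}

    groups: List[Sequence[HRSeries]]
    if config.per_session_clustering:
        groups = [[s] for s in series_list]
    else:
        groups = [series_list]

    models: Dict[int, TwoClusterAnomalyDetector] = {}
    for group in groups:
        for T in config.window_lengths_s:
            tagged = _hr_windows_by_T(group, T, config.overlap_fraction)
            if len(tagged) < MIN_ROWS:
                continue
            X = feature_matrix([w for _, w in tagged])
            det = TwoClusterAnomalyDetector(
                random_state=config.gmm_seed, standardize=config.standardize_hr_features
            ).fit(X)
            models[int(T)] = det
            labels = det.predict(X)
            for (key, w), lab in zip(tagged, labels):
                if lab:
                    per_session[key].append((w.start_s, w.end_s))
                    source_T[key].add(int(T))

    result = {
        key: SMEventSet(
            key=key,
            modality="HR",
            intervals=merge_intervals(ivs) if ivs else [],
            source_T=frozenset(source_T[key]),
        )
        for key, ivs in per_session.items()
    }
    return (result, models) if return_models else result


def detect_sm_hr_single(series: HRSeries, config: PipelineConfig) -> SMEventSet:
    """Convenience wrapper for a single session."""
    return detect_sm_hr(series, config)[series.key]


# ---------------------------------------------------------------------------
# EFE-branch detection

def detect_sm_efe(
    series: EFEFrameSeries | Sequence[EFEFrameSeries], config: PipelineConfig
) -> Dict[SessionKey, SMEventSet]:
    """Frame-level specific moments in the facial-expression stream.

    Unmasked frames are pooled across the student's sessions and clustered;
    each SM-labelled frame contributes [t, t + 1/fps), and intervals closer
    than ``efe_merge_gap_s`` are merged (expression changes unfold over
    seconds, so 1–2 s dropouts inside an episode do not split it).  Merged
    intervals shorter than ``efe_min_duration_s`` are discarded: a moment
    must persist over several frames, and an isolated deviant frame is
    recogniser noise (a blink, a transient occlusion), not an episode.
    """
    series_list = [series] if isinstance(series, EFEFrameSeries) else list(series)
    if not series_list:
        return {}
    frame_dt = 1.0 / config.efe_fps
    tagged_t: List[Tuple[SessionKey, float]] = []
    rows = []
    for s in series_list:
        for t, f in zip(s.valid_times(), s.valid_features()):
            tagged_t.append((s.key, float(t)))
            rows.append(f)
    out: Dict[SessionKey, List[Interval]] = {s.key: [] for s in series_list}
    if len(rows) >= MIN_ROWS:
        X = np.vstack(rows)
        det = TwoClusterAnomalyDetector(
            random_state=config.gmm_seed, standardize=config.standardize_efe_features
        ).fit(X)
        labels = det.predict(X)
        for (key, t), lab in zip(tagged_t, labels):
            if lab:
                out[key].append((t, t + frame_dt))
    def _postprocess(ivs: List[Interval]) -> List[Interval]:
        merged = merge_intervals(ivs, gap=config.efe_merge_gap_s) if ivs else []
        return [iv for iv in merged if iv[1] - iv[0] >= config.efe_min_duration_s]

    return {
        key: SMEventSet(key=key, modality="EFE", intervals=_postprocess(ivs))
        for key, ivs in out.items()
    }
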