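"""GMM anomaly detection, SM-cluster selection, silhouette, detection pipelines."""

import numpy as np
import pytest

import smpipe as sp
from smpipe.detect import (
    TwoClusterAnomalyDetector,
    feature_ablation_silhouettes,
    select_sm_cluster,
    silhouette,
)


def brute_force_silhouette(X, labels):
    """O(n^2) literal evaluation of the silhouette definition."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] == 1:
        X = X.T
    labels = list(labels)
    n = len(labels)
    out = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            out.append(0.0)
            continue
        a = sum(np.linalg.norm(X[i] - X[j]) for j in same) / len(same)
        bs = []
        for lab in set(labels) - {labels[i]}:
            other = [j for j in range(n) if labels[j] == lab]
            bs.append(sum(np.linalg.norm(X[i] - X[j]) for j in other) / len(other))
        b = min(bs)
        denom = max(a, b)
        out.append((b - a) / denom if denom > 0 else 0.0)
    return out


class TestGMMFit:
    def test_minority_weight_recovery(self):
        rng = np.random.default_rng(42)
        X = np.concatenate([rng.normal(0, 0.1, 95), rng.normal(10, 0.1, 5)])[:, None]
        det = sp.fit_two_cluster_gmm(X, seed=0, standardize=False)
        assert det.converged_
        assert min(det.weights_) == pytest.approx(0.05, abs=0.02)
        assert det.sm_component_ == int(np.argmin(det.weights_))

    def test_identical_rows_flagged_nonconverged(self):
        det = sp.fit_two_cluster_gmm(np.ones((20, 3)), seed=0)
        assert not det.converged_
        assert det.predict(np.ones((5, 3))).sum() == 0

    def test_same_seed_same_fit(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 4))
        d1 = sp.fit_two_cluster_gmm(X, seed=7)
        d2 = sp.fit_two_cluster_gmm(X, seed=7)
        np.testing.assert_array_equal(d1.weights_, d2.weights_)
        np.testing.assert_array_equal(d1.means_, d2.means_)
        np.testing.assert_array_equal(d1.predict(X), d2.predict(X))

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            sp.fit_two_cluster_gmm(np.random.default_rng(0).normal(size=(5, 2)), seed=0)

    def test_sklearn_estimator_protocol(self):
        det = TwoClusterAnomalyDetector(random_state=3)
        params = det.get_params()
        assert params["random_state"] == 3
        det.set_params(standardize=False)
        assert det.get_params()["standardize"] is False


class TestSelectSMCluster:
    def test_minority_cluster_selected(self):
        gm = np.zeros(2)
        assert select_sm_cluster([0.95, 0.05], np.zeros((2, 2)), gm) == 1
        assert select_sm_cluster([0.3, 0.7], np.zeros((2, 2)), gm) == 0

    def test_weight_tie_breaks_by_distance_from_global_mean(self):
        means = np.array([[1.0, 0.0], [9.0, 0.0]])
        assert select_sm_cluster([0.5, 0.5], means, np.zeros(2)) == 1


class TestSilhouette:
    def test_two_tight_far_clusters_hand_values(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        res = silhouette(X, [0, 0, 1, 1])
        np.testing.assert_allclose(
            res.per_sample_scores, [0.9048, 0.8947, 0.8947, 0.9048], atol=1e-4
        )
        assert res.mean_score == pytest.approx(0.8997, abs=1e-4)

    def test_coincident_clusters_score_zero(self):
        X = np.zeros((6, 2))
        res = silhouette(X, [0, 0, 0, 1, 1, 1])
        assert res.mean_score == 0.0

    def test_separation_limit_approaches_one(self):
        X = np.array([[0.0], [1e-3], [1e6], [1e6 + 1e-3]])
        assert silhouette(X, [0, 0, 1, 1]).mean_score == pytest.approx(1.0, abs=1e-6)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette(np.random.default_rng(0).normal(size=(10, 2)), [0] * 10)

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            n = rng.integers(5, 60)
            d = rng.integers(1, 5)
            k = rng.integers(2, 4)
            X = rng.normal(size=(n, d))
            labels = rng.integers(0, k, size=n)
            if len(np.unique(labels)) < 2:
                labels[0] = (labels[0] + 1) % k
            res = silhouette(X, labels)
            np.testing.assert_allclose(
                res.per_sample_scores, brute_force_silhouette(X, labels), atol=1e-9
            )

    def test_matches_sklearn_on_multi_point_clusters(self):
        from sklearn.metrics import silhouette_samples

        rng = np.random.default_rng(5)
        X = rng.normal(size=(80, 3))
        labels = rng.integers(0, 3, size=80)
        np.testing.assert_allclose(
            silhouette(X, labels).per_sample_scores,
            silhouette_samples(X, labels),
            atol=1e-9,
        )


class TestFeatureAblation:
    def test_single_informative_feature_ranked_first(self):
        rng = np.random.default_rng(0)
        n = 100
        labels = np.array([0] * 90 + [1] * 10)
        X = rng.normal(size=(n, 6)) * 0.3
        X[labels == 1, 4] += 8.0  # only mu_a separates
        rows = feature_ablation_silhouettes(X, labels)
        singles = [r for r in rows if r[0] in sp.FEATURE_NAMES]
        assert singles[0][0] == "mu_a"

    def test_pure_noise_has_no_strong_feature(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(120, 6))
        labels = rng.integers(0, 2, size=120)
        rows = feature_ablation_silhouettes(X, labels)
        assert all(score < 0.2 for name, score in rows)

    def test_duplicated_informative_feature_ties(self):
        rng = np.random.default_rng(1)
        labels = np.array([0] * 50 + [1] * 50)
        f = rng.normal(size=100) + labels * 5
        X = np.column_stack([f, f])
        rows = dict(feature_ablation_silhouettes(X, labels, feature_names=["f", "f"]))
        assert rows["f"] == pytest.approx(rows["f#2"], abs=1e-12)


class TestDetectSMHR:
    def test_injected_episode_recovered(self, key):
        """A high-dynamics stretch is found with T=150 alone (Jaccard >= 0.5)."""
        cfg_syn = sp.SyntheticConfig(
            n_students=1, n_sessions=1, session_length_s=1800,
            episodes_per_session=1, episode_length_s=150, seed=11,
        )
        # place one episode at a known location by generating and reading truth
        b = sp.generate_session(cfg_syn, key, seed=11)
        cfg = sp.PipelineConfig(window_lengths_s=[150])
        sms = sp.detect_sm_hr(b.hr, cfg)[key]
        (ts, te), = b.truth.intervals
        inter = sum(max(0.0, min(e, te) - max(s, ts)) for s, e in sms.intervals)
        union = (te - ts) + sum(e - s for s, e in sms.intervals) - inter
        assert inter / union >= 0.5

    def test_flat_trace_yields_empty_set(self, flat_series, config):
        sms = sp.detect_sm_hr(flat_series, config)[flat_series.key]
        assert sms.intervals == []

    def test_abutting_windows_merge(self, key):
        # merge semantics checked directly on the event-set constructor
        s = sp.SMEventSet(key, "HR", [(0, 150), (150, 300)], source_T={150, 60})
        assert s.intervals == [(0.0, 300.0)]

    def test_union_monotone_in_T_grid(self, small_cohort):
        series = [b.hr for b in small_cohort]
        small = sp.detect_sm_hr(series, sp.PipelineConfig(window_lengths_s=[120, 150]))
        big = sp.detect_sm_hr(series, sp.PipelineConfig(window_lengths_s=[60, 120, 150, 210]))
        from smpipe.intervals import intersect, total_length
        for k in small:
            # every second flagged with the smaller grid stays flagged with the superset
            a, b = small[k].intervals, big[k].intervals
            assert total_length(intersect(a, b)) == pytest.approx(total_length(a))

    def test_sm_intervals_stay_inside_coverage(self, small_cohort, config):
        sms = sp.detect_sm_hr([b.hr for b in small_cohort], config)
        for b in small_cohort:
            cov = b.hr.coverage
            for s, e in sms[b.key].intervals:
                assert any(cs <= s and e <= ce for cs, ce in cov)


class TestDetectSMEFE:
    def test_shifted_stretch_recovered(self, key, config):
        rng = np.random.default_rng(0)
        feats = rng.dirichlet((1, 1, 1, 1, 1, 1, 24), size=600)
        feats[300:320] = 0.5 * feats[300:320] + 0.5 * np.eye(7)[3]
        series = sp.EFEFrameSeries(
            key=key, frame_times=np.arange(600.0), features=feats,
            quality_mask=np.ones(600, bool),
        )
        sms = sp.detect_sm_efe(series, config)[key]
        covered = sum(max(0.0, min(e, 320) - max(s, 300)) for s, e in sms.intervals)
        assert covered >= 10  # >= 50% of the shifted span

    def test_identical_frames_yield_empty_set(self, key, config):
        feats = np.tile(np.eye(7)[6], (200, 1))
        series = sp.EFEFrameSeries(
            key=key, frame_times=np.arange(200.0), features=feats,
            quality_mask=np.ones(200, bool),
        )
        assert sp.detect_sm_efe(series, config)[key].intervals == []

    def test_merge_gap_rule(self):
        from smpipe.intervals import merge_intervals
        merged = merge_intervals([(10, 11), (12, 13)], gap=2)
        assert merged == [(10.0, 13.0)]

    def test_intervals_stay_inside_frame_span(self, small_cohort, config):
        sms = sp.detect_sm_efe([b.efe for b in small_cohort], config)
        for b in small_cohort:
            t0, t1 = b.efe.frame_times[0], b.efe.frame_times[-1] + 1.0
            for s, e in sms[b.key].intervals:
                assert t0 <= s < e <= t1
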