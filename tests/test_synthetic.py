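"""Generator determinism, realism constraints, and detection evaluation."""

import numpy as np
import pytest
from scipy import stats

import smpipe as sp

K = sp.SessionKey("S1", "s1")


class TestGenerateSession:
    def test_truth_has_configured_episode_count(self, small_cohort):
        for b in small_cohort:
            assert len(b.truth.intervals) == 5
            L = 4800
            assert all(0 <= s < e <= L for s, e in b.truth.intervals)

    def test_same_seed_is_byte_identical(self, tmp_path):
        from smpipe import io as smio

        cfg = sp.SyntheticConfig(n_students=1, n_sessions=1, session_length_s=600,
                                 episodes_per_session=1, seed=5)
        out = []
        for tag in ("a", "b"):
            b = sp.generate_session(cfg, K, seed=99)
            p = tmp_path / f"hr_{tag}.csv"
            smio.write_hr_csv(b.hr, p)
            out.append(p.read_bytes())
        assert out[0] == out[1]

    def test_bpm_stays_in_physiological_range(self):
        cfg = sp.SyntheticConfig(n_students=1, n_sessions=1, noise_sd_bpm=30.0,
                                 hr_baseline_range_bpm=(60, 61), seed=0)
        b = sp.generate_session(cfg, K, seed=1)
        assert b.hr.bpm.min() >= 30.0 and b.hr.bpm.max() <= 220.0

    def test_unit_multiplier_is_null_for_dynamics(self):
        """With multiplier 1, episode windows' mu_a matches baseline windows'."""
        from smpipe.hr import feature_matrix, segment_windows
        from smpipe.intervals import overlap_length

        cfg = sp.SyntheticConfig(n_students=1, n_sessions=1, episode_dynamics_multiplier=1.0,
                                 session_length_s=4800, seed=2)
        b = sp.generate_session(cfg, K, seed=2)
        ws = segment_windows(b.hr, 60, 0.5)
        X = feature_matrix(ws)
        in_ep = np.array([
            max((overlap_length((w.start_s, w.end_s), iv) for iv in b.truth.intervals), default=0) >= 60
            for w in ws
        ])
        base_mu_a = X[~in_ep, 4][:50]
        ep_mu_a = X[in_ep, 4]
        assert len(ep_mu_a) >= 5
        p = stats.mannwhitneyu(base_mu_a, ep_mu_a).pvalue
        assert p > 0.01

    def test_obs_track_mixes_salient_and_routine(self, small_cohort):
        all_events = [e for b in small_cohort for e in b.obs.events]
        assert any(e.salient for e in all_events)
        assert all(e.end_s > e.start_s for e in all_events)


class TestCohort:
    def test_shape_and_distinct_sessions(self):
        cfg = sp.SyntheticConfig(n_students=2, n_sessions=2, session_length_s=600,
                                 episodes_per_session=1, seed=4)
        bundles = sp.generate_cohort(cfg)
        assert len(bundles) == 4
        keys = {b.key for b in bundles}
        assert len(keys) == 4
        # per-student baseline shared across sessions, distinct across students
        by_student = {}
        for b in bundles:
            by_student.setdefault(b.key.student_id, set()).add(b.baseline_bpm)
        assert all(len(v) == 1 for v in by_student.values())

    def test_recall_increases_with_dynamics_multiplier(self):
        """Stronger episode dynamics make HR detection recall rise on average."""
        recalls = []
        for mult in (1.0, 2.0, 3.0):
            per_seed = []
            for seed in range(3):
                cfg = sp.SyntheticConfig(n_students=1, n_sessions=1,
                                         episode_dynamics_multiplier=mult, seed=seed)
                bundles = sp.generate_cohort(cfg)
                pcfg = sp.PipelineConfig(window_lengths_s=[90, 120])
                sms = sp.detect_sm_hr([b.hr for b in bundles], pcfg)
                per_seed.append(np.mean([
                    sp.evaluate_detection(sms[b.key], b.truth).recall for b in bundles
                ]))
            recalls.append(np.mean(per_seed))
        assert recalls[2] > recalls[0]
        assert recalls[2] >= 0.8


class TestEvaluateDetection:
    def test_identity_is_perfect(self):
        t = sp.SMEventSet(K, "HR", [(0, 100), (200, 300)])
        ev = sp.evaluate_detection(t, t)
        assert (ev.precision, ev.recall, ev.f1) == (1.0, 1.0, 1.0)

    def test_empty_detection_scores_zero(self):
        truth = sp.SMEventSet(K, "HR", [(0, 100)])
        ev = sp.evaluate_detection(sp.SMEventSet(K, "HR", []), truth)
        assert (ev.precision, ev.recall) == (0.0, 0.0)

    def test_partial_matching_arithmetic(self):
        det = sp.SMEventSet(K, "HR", [(0, 100)])
        truth = sp.SMEventSet(K, "HR", [(50, 150), (300, 400)])
        ev = sp.evaluate_detection(det, truth)
        assert (ev.precision, ev.recall) == (1.0, 0.5)

    def test_each_truth_matched_at_most_once(self):
        det = sp.SMEventSet(K, "HR", [(0, 50), (60, 100)])
        truth = sp.SMEventSet(K, "HR", [(0, 100)])
        ev = sp.evaluate_detection(det, truth)
        assert ev.n_matched == 1
        assert ev.precision == 0.5 and ev.recall == 1.0
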