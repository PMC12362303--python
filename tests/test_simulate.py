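"""Generator behavior: event streams, motion confound, BOLD mixing, gaze,
behavioral chain."""

import numpy as np
import pytest

from navdyn.config import CohortConfig
from navdyn.events import aggregate_gaze
from navdyn.prep import framewise_displacement_frames
from navdyn.simulate import (
    generate_behavior,
    generate_cohort,
    generate_design,
    generate_event_streams,
    generate_gaze,
    generate_ground_truth,
    generate_motion,
)
from navdyn.simulate.bold import canonical_signals, simulate_segments
from navdyn.simulate.design import LANDMARK_CONDITIONS, NAV_EXCLUDED_FRAMES
from navdyn.simulate.rng import substream
from navdyn.stats import mediation


def _corr_last(a, b):
    a = a - a.mean(-1, keepdims=True)
    b = b - b.mean(-1, keepdims=True)
    return (a * b).sum(-1) / np.sqrt((a * a).sum(-1) * (b * b).sum(-1))


class TestEventStreams:
    def test_turn_counts_between_4_and_8(self):
        cfg = CohortConfig()
        d = generate_design(cfg, 0)
        for s in generate_event_streams(d, cfg, 0):
            assert 4 <= s.n_turns <= 8

    def test_stationary_margins_have_zero_angular_velocity(self):
        cfg = CohortConfig()
        d = generate_design(cfg, 1)
        for s in generate_event_streams(d, cfg, 1):
            assert np.all(s.angular_velocity[s.time_s < 2.0] == 0)
            assert np.all(s.angular_velocity[s.time_s >= 58.0] == 0)
            assert np.all(s.angular_velocity >= 0)
            assert s.time_s.size == 600

    def test_gaze_ratio_zero_without_landmarks_and_bounded_otherwise(self):
        cfg = CohortConfig()
        d = generate_design(cfg, 2)
        for s in generate_event_streams(d, cfg, 2):
            if s.condition in LANDMARK_CONDITIONS:
                assert s.gaze_ratio.max() > 0.3
                assert s.gaze_ratio.min() >= 0 and s.gaze_ratio.max() <= 1
            else:
                assert np.all(s.gaze_ratio == 0)


class TestMotion:
    def _age_fd_corr(self, seed, **kw):
        cfg = CohortConfig(**kw)
        d = generate_design(cfg, seed)
        t = generate_ground_truth(d, cfg, seed)
        m = generate_motion(d, t, cfg, seed)
        fd = framewise_displacement_frames(m).mean(axis=(1, 2))
        return np.corrcoef(d.ages, fd)[0, 1]

    def test_default_age_fd_correlation_near_half(self):
        # seed-averaged cohort replications; generative target r = 0.493
        rs = [self._age_fd_corr(s) for s in range(25)]
        assert abs(np.mean(rs) - 0.493) < 0.1

    def test_zero_gamma_removes_the_confound(self):
        rs = [self._age_fd_corr(s, motion_gamma=0.0) for s in range(10)]
        assert abs(np.mean(rs)) < 0.15

    def test_motion_disabled_gives_zero_fd_everywhere(self):
        cfg = CohortConfig(n_young=3, n_old=3, motion_enabled=False)
        d = generate_design(cfg, 0)
        t = generate_ground_truth(d, cfg, 0)
        m = generate_motion(d, t, cfg, 0)
        assert np.all(framewise_displacement_frames(m) == 0)


class TestBoldMixing:
    def test_noise_free_full_coupling_reproduces_canonical_exactly(self):
        cfg = CohortConfig(
            n_young=2, n_old=2, coupling_w_fixed=1.0, noise_sd=0.0,
            motion_enabled=False, drift_amplitude_pct=0.0,
            regions=CohortConfig().regions[:4],
        )
        d = generate_design(cfg, 0)
        t = generate_ground_truth(d, cfg, 0)
        st = generate_event_streams(d, cfg, 0)
        can = canonical_signals(d, st, t, cfg, seed=0)
        seg = simulate_segments(d, can, t, cfg, substream(0, "bold_noise"))
        for i in range(d.n_participants):
            assert np.allclose(seg[i], can.g, atol=1e-12)

    def test_zero_coupling_gives_near_zero_mean_correlation(self):
        cfg = CohortConfig(
            n_young=6, n_old=6, coupling_w_fixed=0.0,
            regions=CohortConfig().regions[:6],
        )
        d = generate_design(cfg, 3)
        t = generate_ground_truth(d, cfg, 3)
        st = generate_event_streams(d, cfg, 3)
        can = canonical_signals(d, st, t, cfg, seed=3)
        seg = simulate_segments(d, can, t, cfg, substream(3, "bold_noise"))
        r = _corr_last(seg[..., NAV_EXCLUDED_FRAMES:], can.g[None, :, :, NAV_EXCLUDED_FRAMES:])
        assert abs(r.mean()) < 0.02

    def test_population_correlation_tracks_w(self):
        # corr(w*g + sqrt(1-w^2)*eps, g) = w for unit-variance components
        cfg = CohortConfig(n_young=10, n_old=10, coupling_w_fixed=0.6)
        d = generate_design(cfg, 2)
        t = generate_ground_truth(d, cfg, 2)
        st = generate_event_streams(d, cfg, 2)
        can = canonical_signals(d, st, t, cfg, seed=2)
        seg = simulate_segments(d, can, t, cfg, substream(2, "bold_noise"))
        r = _corr_last(seg[..., NAV_EXCLUDED_FRAMES:], can.g[None, :, :, NAV_EXCLUDED_FRAMES:])
        assert abs(r.mean() - 0.6) < 0.05

    def test_mismatched_streams_raise_schema_error(self):
        from navdyn.errors import SchemaError

        cfg = CohortConfig(n_young=2, n_old=2)
        d = generate_design(cfg, 0)
        t = generate_ground_truth(d, cfg, 0)
        st = generate_event_streams(d, cfg, 0)
        with pytest.raises(SchemaError):
            canonical_signals(d, st[:-1], t, cfg, seed=0)


class TestGaze:
    def test_no_landmark_episodes_have_all_zero_flags(self):
        cfg = CohortConfig(n_young=2, n_old=2, n_gaze_participants=8)
        d = generate_design(cfg, 1)
        st = generate_event_streams(d, cfg, 1)
        gaze = generate_gaze(d, st, cfg, 1)
        for s in st:
            if s.condition not in LANDMARK_CONDITIONS:
                assert np.all(gaze[s.episode] == 0)

    def test_certain_gaze_gives_unit_ratio_after_aggregation(self):
        cfg = CohortConfig(
            n_young=2, n_old=2, n_gaze_participants=4,
            gaze_on_prob_floor=1.0, gaze_on_prob_gain=0.0,
        )
        d = generate_design(cfg, 1)
        st = generate_event_streams(d, cfg, 1)
        gaze = generate_gaze(d, st, cfg, 1)
        for s in st:
            if s.condition in LANDMARK_CONDITIONS:
                assert np.all(aggregate_gaze(gaze[s.episode]) == 1.0)

    def test_aggregated_ratio_tracks_latent_profile(self):
        cfg = CohortConfig(n_young=2, n_old=2)
        d = generate_design(cfg, 4)
        st = generate_event_streams(d, cfg, 4)
        gaze = generate_gaze(d, st, cfg, 4)
        rs = []
        for s in st:
            if s.condition in LANDMARK_CONDITIONS:
                ratio = aggregate_gaze(gaze[s.episode])
                rs.append(np.corrcoef(ratio, s.gaze_ratio)[0, 1])
        assert np.mean(rs) > 0.5


class TestBehavior:
    def test_null_paths_remove_age_performance_link(self):
        cfg = CohortConfig(mediation_b=0.0, mediation_c_prime=0.0)
        rs = []
        for s in range(10):
            d = generate_design(cfg, s)
            t = generate_ground_truth(d, cfg, s)
            beh = generate_behavior(d, t, cfg, s)
            rs.append(np.corrcoef(d.ages, beh.performance_latent)[0, 1])
        assert abs(np.mean(rs)) < 0.1

    def test_negative_total_effect_recovered_in_most_replications(self):
        cfg = CohortConfig(mediation_a=-0.5, mediation_b=0.5, mediation_c_prime=-0.4)
        neg = 0
        n_rep = 60
        for s in range(n_rep):
            d = generate_design(cfg, s)
            t = generate_ground_truth(d, cfg, s)
            beh = generate_behavior(d, t, cfg, s)
            res = mediation(
                d.ages, t.mediator, beh.performance_latent, t.motion_propensity
            )
            neg += res.total_c < 0
        assert neg / n_rep > 0.95

    def test_missing_response_fraction_is_honored(self):
        cfg = CohortConfig(missing_response_fraction=0.1)
        d = generate_design(cfg, 5)
        t = generate_ground_truth(d, cfg, 5)
        beh = generate_behavior(d, t, cfg, 5)
        frac = 1.0 - beh.responses["responded"].mean()
        assert abs(frac - 0.1) < 0.03


def test_same_seed_reproduces_cohort_byte_for_byte(small_cfg):
    a = generate_cohort(small_cfg, seed=5)
    b = generate_cohort(small_cfg, seed=5)
    assert np.array_equal(a.bold, b.bold)
    assert np.array_equal(a.motion, b.motion)
    assert a.behavior.responses.equals(b.behavior.responses)
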