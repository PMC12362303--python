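"""Canonical dynamics, ICS, decoding, and their permutation inference."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from navdyn.config import CohortConfig
from navdyn.errors import InvalidConfigError
from navdyn.ics import (
    SegmentArray,
    accuracy_by_episode,
    canonical_dynamics,
    condition_contrast,
    cross_ics,
    decode_episodes,
    decoding_permutation_test,
    fisher_z,
    ics,
    ics_permutation_test,
    ics_table,
)
from navdyn.pipeline import prep_stage
from navdyn.ics import build_segment_array
from navdyn.simulate import generate_cohort

CLIP_Z = np.arctanh(1 - 1e-7)


def _segments(data):
    n_p, n_k, n_e, _ = data.shape
    return SegmentArray(
        data=data,
        participants=tuple(f"sub-{i:03d}" for i in range(n_p)),
        regions=tuple(CohortConfig().regions[:n_k]),
        episodes=tuple(range(n_e)),
    )


class TestCanonicalDynamics:
    def test_mean_excludes_the_tested_participant(self):
        seg = np.array([[1.0, 0], [2.0, 0], [3.0, 0]])
        assert canonical_dynamics(seg, exclude=0)[0] == pytest.approx(2.5)

    def test_identical_participants_reproduce_any_individual(self, rng):
        x = rng.standard_normal(26)
        seg = np.tile(x, (5, 1))
        assert np.allclose(canonical_dynamics(seg, exclude=2), x)

    def test_matches_brute_force_mean(self, rng):
        seg = rng.standard_normal((10, 26))
        out = canonical_dynamics(seg, exclude=4)
        brute = np.stack([seg[i] for i in range(10) if i != 4]).mean(axis=0)
        assert np.allclose(out, brute)

    def test_single_participant_rejected(self):
        with pytest.raises(InvalidConfigError):
            canonical_dynamics(np.ones((1, 26)), exclude=0)


class TestICS:
    def test_identical_segment_hits_the_clip_bound(self, rng):
        x = rng.standard_normal(26)
        r, z = ics(x, x)
        assert r == pytest.approx(1.0)
        assert z == pytest.approx(CLIP_Z)

    def test_orthogonal_sin_cos_gives_near_zero(self):
        t = np.arange(26)
        r, z = ics(np.sin(2 * np.pi * t / 13), np.cos(2 * np.pi * t / 13))
        assert abs(z) < 0.05

    def test_fisher_z_closed_form_at_half(self, rng):
        # construct a pair with sample correlation exactly 0.5
        x = rng.standard_normal(26)
        x = (x - x.mean()) / x.std()
        y = rng.standard_normal(26)
        y -= y.mean()
        y -= x * (x @ y) / (x @ x)  # orthogonalize
        y /= y.std()
        target = 0.5
        pair = target * x + np.sqrt(1 - target**2) * y
        r, z = ics(pair, x)
        assert r == pytest.approx(0.5, abs=1e-12)
        assert z == pytest.approx(0.5493, abs=1e-4)

    def test_zero_variance_segment_rejected(self):
        with pytest.raises(InvalidConfigError):
            ics(np.ones(26), np.arange(26.0))

    @given(
        st.floats(min_value=0.1, max_value=20.0),
        st.floats(min_value=-10.0, max_value=10.0),
    )
    def test_positive_affine_invariance(self, a, b):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal((2, 26))
        r1, _ = ics(x, y)
        r2, _ = ics(a * x + b, y)
        assert r1 == pytest.approx(r2, abs=1e-9)


class TestCrossICSAndDecoding:
    def test_cross_matrix_matches_per_pair_recomputation(self, rng):
        data = rng.standard_normal((5, 2, 4, 26))
        seg = _segments(data)
        C = cross_ics(seg)
        # brute force a few entries
        for i, k, e, f in [(0, 0, 1, 2), (3, 1, 0, 0), (4, 0, 3, 1)]:
            template = np.delete(data[:, k, f, :], i, axis=0).mean(axis=0)
            r, _ = ics(data[i, k, e], template)
            assert C[i, k, e, f] == pytest.approx(r, abs=1e-10)

    def test_ties_resolve_to_lowest_index_and_flag(self, rng):
        base = rng.standard_normal(26)
        data = rng.standard_normal((3, 1, 3, 26)) * 0.01
        # all participants share identical segments for episodes 1 and 2
        for e in (1, 2):
            data[:, 0, e, :] = base
        seg = _segments(data)
        dec = decode_episodes(seg)
        d = dec[(dec.participant_id == "sub-000") & (dec.true_episode == 1)]
        assert int(d.predicted_episode.iloc[0]) == 1  # lowest of the tied {1, 2}
        assert bool(d.tie_flag.iloc[0])

    def test_noise_free_cohort_decodes_perfectly(self):
        cfg = CohortConfig(
            n_young=3, n_old=3, coupling_w_fixed=1.0, noise_sd=0.0,
            motion_enabled=False, drift_amplitude_pct=0.0,
            regions=CohortConfig().regions[:4],
        )
        cohort = generate_cohort(cfg, seed=0, with_gaze=False)
        segs = build_segment_array(prep_stage(cohort).zscored_runs, cohort.design)
        dec = decode_episodes(segs)
        assert dec["correct"].all()
        tab = ics_table(segs)
        assert np.allclose(tab["z"], CLIP_Z, atol=1e-6)

    def test_zero_coupling_decodes_at_chance(self):
        cfg = CohortConfig(
            n_young=8, n_old=8, coupling_w_fixed=0.0,
            regions=CohortConfig().regions[:12],
        )
        cohort = generate_cohort(cfg, seed=1, with_gaze=False)
        segs = build_segment_array(prep_stage(cohort).zscored_runs, cohort.design)
        dec = decode_episodes(segs)
        acc = dec["correct"].mean()  # 16 * 12 * 24 = 4608 decisions
        assert acc == pytest.approx(1 / 24, abs=3 * np.sqrt(0.04 * 0.96 / 4608) + 0.003)

    def test_accuracy_increases_with_coupling(self):
        # decoding beats chance whenever w > 0 and latents are episode-unique
        accs = []
        for w in (0.0, 0.3, 0.6, 0.9):
            cfg = CohortConfig(
                n_young=5, n_old=5, coupling_w_fixed=w,
                regions=CohortConfig().regions[:6],
            )
            cohort = generate_cohort(cfg, seed=2, with_gaze=False)
            segs = build_segment_array(prep_stage(cohort).zscored_runs, cohort.design)
            accs.append(decode_episodes(segs)["correct"].mean())
        assert all(b > a for a, b in zip(accs, accs[1:]))
        assert accs[-1] > 0.5


class TestPermutationTests:
    def test_pvalues_respect_add_one_bounds(self, rng):
        seg = _segments(rng.standard_normal((4, 2, 6, 26)))
        for df in (
            ics_permutation_test(seg, n_perm=50, seed=0),
            decoding_permutation_test(seg, n_perm=50, seed=0),
        ):
            assert (df.p_perm >= 1 / 51).all()
            assert (df.p_perm <= 1.0).all()

    def test_observed_below_null_median_gives_large_p(self, rng):
        # alternating-sign construction: every matched pair anticorrelates
        # with its template while mismatched pairs stay near zero
        base = rng.standard_normal((6, 26))
        data = np.empty((6, 1, 6, 26))
        for i in range(6):
            sign = 1.0 if i % 2 == 0 else -1.0
            data[i, 0] = sign * base + 0.1 * rng.standard_normal((6, 26))
        seg = _segments(data)
        df = ics_permutation_test(seg, n_perm=300, seed=1)
        assert (df.p_perm > 0.5).all()

    def test_perfect_decoder_reaches_minimal_p(self):
        cfg = CohortConfig(
            n_young=3, n_old=3, coupling_w_fixed=1.0, noise_sd=0.0,
            motion_enabled=False, drift_amplitude_pct=0.0,
            regions=CohortConfig().regions[:2],
        )
        cohort = generate_cohort(cfg, seed=0, with_gaze=False)
        segs = build_segment_array(prep_stage(cohort).zscored_runs, cohort.design)
        df = decoding_permutation_test(segs, n_perm=200, seed=0)
        assert np.allclose(df.p_perm, 1 / 201)

    def test_null_mean_accuracy_is_chance(self, rng):
        seg = _segments(rng.standard_normal((6, 2, 24, 26)))
        df = decoding_permutation_test(seg, n_perm=2000, seed=3)
        assert np.allclose(df.null_mean_accuracy, 1 / 24, atol=0.005)

    def test_same_seed_reproduces_pvalues(self, segments):
        a = ics_permutation_test(segments, n_perm=100, seed=9)
        b = ics_permutation_test(segments, n_perm=100, seed=9)
        assert np.array_equal(a.p_perm, b.p_perm)

    @pytest.mark.parametrize("strategy", ["pairwise_same", "pairwise_any"])
    def test_pairwise_strategies_run(self, rng, strategy):
        seg = _segments(rng.standard_normal((4, 1, 6, 26)))
        df = ics_permutation_test(seg, n_perm=50, seed=0, strategy=strategy)
        assert len(df) == 1
        assert df.p_perm.iloc[0] >= 1 / 51

    def test_invalid_n_perm_rejected(self, rng):
        seg = _segments(rng.standard_normal((3, 1, 4, 26)))
        with pytest.raises(InvalidConfigError):
            ics_permutation_test(seg, n_perm=0)


class TestConditionContrast:
    def test_six_versus_six_has_df_10(self, rng):
        t, df, p = condition_contrast(rng.standard_normal(12), np.arange(12) < 6)
        assert df == 10

    def test_identical_groups_give_zero_t(self):
        acc = np.array([0.1, 0.2, 0.3, 0.1, 0.2, 0.3])
        t, df, p = condition_contrast(acc, np.arange(6) < 3)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_textbook_pooled_formula(self):
        acc = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        t, df, p = condition_contrast(acc, np.arange(6) < 3)
        # pooled: means 2 and 5, s_p^2 = 1, t = -3 / sqrt(1*(1/3+1/3))
        assert df == 4
        assert t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), abs=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(InvalidConfigError):
            condition_contrast(np.ones(3), np.array([True, False, False]))


def test_ics_monotone_in_coupling_through_full_pipeline():
    means = []
    for w in (0.0, 0.3, 0.6, 0.9):
        vals = []
        for seed in (0, 1):
            cfg = CohortConfig(
                n_young=5, n_old=5, coupling_w_fixed=w,
                regions=CohortConfig().regions[:6],
            )
            cohort = generate_cohort(cfg, seed=seed, with_gaze=False)
            segs = build_segment_array(prep_stage(cohort).zscored_runs, cohort.design)
            vals.append(ics_table(segs)["z"].mean())
        means.append(np.mean(vals))
    assert all(b > a for a, b in zip(means, means[1:]))
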