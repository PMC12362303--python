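"""Signal conditioning: percent change, confounds, z-scoring, windows,
activation and performance scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from navdyn.config import CohortConfig
from navdyn.errors import DegenerateSignalError, InvalidConfigError, SchemaError
from navdyn.prep import (
    ConfoundMatrix,
    RunSeries,
    average_activation,
    condition_run,
    dct_basis,
    expand_motion,
    extract_windows,
    framewise_displacement,
    percent_signal_change,
    regress_confounds,
    spatial_memory_performance,
    zscore_run,
)
from navdyn.simulate import generate_design


def _run(values, stage="raw", regions=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1:
        values = values.T
    regions = regions or tuple(f"r{i}" for i in range(values.shape[1]))
    return RunSeries(
        participant_id="sub-001",
        run_index=0,
        frame_times_s=np.arange(values.shape[0]) * 2.0,
        values=values,
        regions=regions,
        stage=stage,
    )


class TestPercentSignalChange:
    def test_constant_series_maps_to_zero(self):
        out = percent_signal_change(_run([100, 100, 100, 100]))
        assert np.allclose(out.values, 0.0)
        assert out.stage == "psc"

    def test_symmetric_values_around_mean(self):
        out = percent_signal_change(_run([90, 110]))
        assert np.allclose(out.values.ravel(), [-10.0, 10.0])

    def test_matches_two_pass_oracle(self, rng):
        x = 1000 + 50 * rng.standard_normal((300, 3))
        out = percent_signal_change(_run(x))
        oracle = np.empty_like(x)
        for j in range(x.shape[1]):
            m = sum(x[:, j]) / len(x)  # independent two-pass mean
            for i in range(x.shape[0]):
                oracle[i, j] = (x[i, j] - m) / m * 100.0
        assert np.allclose(out.values, oracle, atol=1e-12)

    def test_zero_mean_region_fails_loudly(self):
        with pytest.raises(DegenerateSignalError, match="r0"):
            percent_signal_change(_run([-1.0, 1.0]))

    @given(st.floats(min_value=0.1, max_value=100.0))
    def test_scale_invariance(self, scale):
        x = np.linspace(900, 1100, 20)
        a = percent_signal_change(_run(x)).values
        b = percent_signal_change(_run(scale * x)).values
        assert np.allclose(a, b, atol=1e-9)


class TestMotionExpansion:
    def test_constant_params_zero_out_derivative_terms(self):
        params = np.ones((5, 6)) * 0.3
        out = expand_motion(params)
        assert out.shape == (5, 24)
        assert np.allclose(out[:, 6:12], 0)  # derivatives
        assert np.allclose(out[:, 18:24], 0)  # squared derivatives

    def test_hand_arithmetic_single_column(self):
        params = np.zeros((3, 6))
        params[:, 0] = [0, 1, 3]
        out = expand_motion(params)
        assert np.allclose(out[:, 0], [0, 1, 3])
        assert np.allclose(out[:, 6], [0, 1, 2])
        assert np.allclose(out[:, 12], [0, 1, 9])
        assert np.allclose(out[:, 18], [0, 1, 4])

    def test_matches_column_by_column_oracle(self, rng):
        params = rng.standard_normal((50, 6))
        out = expand_motion(params)
        for j in range(6):
            d = np.concatenate([[0.0], np.diff(params[:, j])])
            assert np.allclose(out[:, j], params[:, j])
            assert np.allclose(out[:, 6 + j], d)
            assert np.allclose(out[:, 12 + j], params[:, j] ** 2)
            assert np.allclose(out[:, 18 + j], d**2)

    def test_wrong_column_count_rejected(self):
        with pytest.raises(SchemaError):
            expand_motion(np.zeros((5, 5)))


class TestFramewiseDisplacement:
    def test_no_motion_gives_zero_fd(self):
        assert np.all(framewise_displacement(np.zeros((10, 6))) == 0)

    def test_unit_translation_step(self):
        p = np.zeros((4, 6))
        p[2:, 1] = 1.0  # 1 mm step at frame 2
        fd = framewise_displacement(p)
        assert fd[0] == 0 and fd[1] == 0
        assert fd[2] == pytest.approx(1.0)

    def test_rotation_scaled_by_50mm_radius(self):
        p = np.zeros((3, 6))
        p[1:, 4] = 0.01  # 0.01 rad step
        fd = framewise_displacement(p)
        assert fd[1] == pytest.approx(0.5)


class TestDCTBasis:
    def test_closed_form_n8_first_column(self):
        cols = dct_basis(8, 1)
        t = np.arange(8)
        assert np.allclose(cols[:, 0], np.cos(np.pi * (2 * t + 1) / 16))

    def test_columns_orthogonal_and_zero_mean(self):
        cols = dct_basis(306, 5)
        assert cols.shape == (306, 5)
        assert np.allclose(cols.mean(axis=0), 0, atol=1e-12)
        gram = cols.T @ cols
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) / np.max(np.abs(gram)) < 1e-9

    def test_too_many_components_rejected(self):
        with pytest.raises(InvalidConfigError):
            dct_basis(5, 5)


class TestConfoundRegression:
    def _confounds(self, rng, n=60):
        walk = np.cumsum(0.01 * rng.standard_normal((n, 6)), axis=0)
        return ConfoundMatrix.build(walk)

    def test_pure_drift_signal_is_annihilated(self, rng):
        conf = self._confounds(rng)
        signal = 3.0 * conf.values[:, [25]]  # dct_1 column
        run = _run(signal, stage="psc")
        out = regress_confounds(run, conf)
        assert np.max(np.abs(out.values)) < 1e-9

    def test_residuals_orthogonal_to_every_confound(self, rng):
        conf = self._confounds(rng)
        run = _run(rng.standard_normal((60, 4)), stage="psc")
        out = regress_confounds(run, conf)
        dots = conf.values.T @ out.values
        scale = np.linalg.norm(conf.values, axis=0)[:, None] * np.linalg.norm(
            out.values, axis=0
        )
        assert np.max(np.abs(dots) / np.maximum(scale, 1e-12)) < 1e-6

    def test_matches_normal_equations_oracle(self, rng):
        conf = self._confounds(rng)
        y = rng.standard_normal(60)
        out = regress_confounds(_run(y, stage="psc"), conf)
        X = np.column_stack([np.ones(60), conf.values])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(out.values.ravel(), y - X @ beta, atol=1e-8)

    def test_confound_count_is_30(self, rng):
        conf = self._confounds(rng)
        assert conf.values.shape[1] == 30
        assert len(conf.columns) == 30


class TestZScore:
    def test_already_standard_series_unchanged(self):
        out = zscore_run(_run([-1.0, 0.0, 1.0], stage="cleaned"))
        assert np.allclose(out.values.ravel(), [-1, 0, 1])

    @given(
        st.floats(min_value=0.1, max_value=10.0),
        st.floats(min_value=-5.0, max_value=5.0),
    )
    def test_affine_invariance(self, a, b):
        x = np.sin(np.arange(30))
        za = zscore_run(_run(x, stage="cleaned")).values
        zb = zscore_run(_run(a * x + b, stage="cleaned")).values
        assert np.allclose(za, zb, atol=1e-9)

    def test_moments_after_zscoring(self, rng):
        out = zscore_run(_run(rng.standard_normal(200), stage="cleaned"))
        assert abs(out.values.mean()) < 1e-12
        assert abs(out.values.std(ddof=1) - 1) < 1e-12

    def test_zero_variance_fails_loudly(self):
        with pytest.raises(DegenerateSignalError):
            zscore_run(_run([2.0, 2.0, 2.0], stage="cleaned"))

    def test_stage_order_is_enforced(self):
        with pytest.raises(SchemaError):
            zscore_run(_run([1.0, 2.0], stage="raw"))


class TestWindowsAndActivation:
    def test_windows_on_generated_design(self, small_cfg):
        design = generate_design(small_cfg, 0)
        run = _run(np.random.default_rng(0).standard_normal((306, 2)) + 100)
        z = condition_run(run, np.zeros((306, 6)))
        windows = extract_windows(z, design)
        assert len(windows) == 6
        for w in windows:
            assert w.all_navigation_frames.size == 30
            assert w.navigation_frames.size == 26
            assert w.baseline_frames.size == 4

    def test_events_past_run_end_raise(self, small_cfg):
        design = generate_design(small_cfg, 0)
        short = _run(np.random.default_rng(0).standard_normal((100, 2)))
        with pytest.raises(Exception):
            extract_windows(short, design)

    def test_activation_is_nav_minus_baseline(self, small_cfg):
        design = generate_design(small_cfg, 0)
        values = np.full((306, 1), 0.5)
        run = _run(values, stage="psc")
        windows = extract_windows(run, design)
        w = windows[0]
        run.values[w.navigation_frames] = 2.0
        run.values[w.baseline_frames] = 0.5
        act = average_activation(run, [w])
        assert act["activation"].iloc[0] == pytest.approx(1.5)

    def test_identical_nav_and_baseline_gives_zero(self, small_cfg):
        design = generate_design(small_cfg, 0)
        run = _run(np.full((306, 1), 0.7), stage="psc")
        act = average_activation(run, extract_windows(run, design))
        assert np.allclose(act["activation"], 0.0)


class TestPerformance:
    def _responses(self, records):
        return pd.DataFrame(
            records, columns=["participant_id", "episode", "responded", "correct"]
        )

    def test_all_correct_with_one_excluded_episode(self):
        rows = [("sub-001", e, True, True) for e in range(24)]
        perf = spatial_memory_performance(self._responses(rows), excluded_episodes=(5,))
        assert perf["sub-001"] == pytest.approx(1.0)

    def test_missing_responses_score_incorrect(self):
        rows = (
            [("sub-001", e, True, True) for e in range(12)]
            + [("sub-001", e, True, False) for e in range(12, 18)]
            + [("sub-001", e, False, False) for e in range(18, 24)]
        )
        perf = spatial_memory_performance(self._responses(rows))
        assert perf["sub-001"] == pytest.approx(0.5)

    def test_all_missing_gives_zero(self):
        rows = [("sub-001", e, False, False) for e in range(24)]
        perf = spatial_memory_performance(self._responses(rows))
        assert perf["sub-001"] == 0.0
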