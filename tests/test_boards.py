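"""Board force processing: filtering, per-board CoP, two-board combination."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from posturofall.boards import (
    BoardForceTrace,
    BoardGeometry,
    CoPTrace,
    DegenerateLoadError,
    TrialConfig,
    board_cop,
    combine_boards,
    moving_average,
    preprocess_trial,
    read_force_table,
    write_force_table,
)

from conftest import random_force_trace


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        out = moving_average(np.full(40, 3.7), 15)
        np.testing.assert_allclose(out, 3.7)

    def test_window_one_is_identity(self, rng):
        x = rng.standard_normal(25)
        np.testing.assert_array_equal(moving_average(x, 1), x)

    def test_matches_per_point_loop_oracle(self, rng):
        x = rng.standard_normal(30)
        window = 5
        half = window // 2
        expected = np.empty_like(x)
        for i in range(x.size):
            h = min(half, i, x.size - 1 - i)  # symmetric shrink at edges
            expected[i] = x[i - h : i + h + 1].mean()
        np.testing.assert_allclose(moving_average(x, window), expected)

    @pytest.mark.parametrize("window", [0, 2, 14, 101])
    def test_invalid_window_rejected(self, rng, window):
        with pytest.raises(ValueError):
            moving_average(rng.standard_normal(50), window)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        data=st.lists(
            st.floats(-100, 100, allow_nan=False), min_size=9, max_size=40
        ),
        shift=st.floats(-50, 50, allow_nan=False),
        scale=st.floats(0.1, 10),
    )
    def test_linear_and_shift_equivariant(self, data, shift, scale):
        """The filter is linear and commutes with additive constants."""
        x = np.asarray(data)
        base = moving_average(x, 9)
        np.testing.assert_allclose(
            moving_average(scale * x + shift, 9), scale * base + shift, atol=1e-9
        )


class TestBoardCop:
    def test_equal_forces_center(self, geometry):
        trace = BoardForceTrace(forces=np.full((50, 4), 100.0), fs=100.0)
        cop = board_cop(trace, geometry)
        np.testing.assert_allclose(cop.ap, 0.0, atol=1e-12)
        np.testing.assert_allclose(cop.ml, 0.0, atol=1e-12)

    def test_corner_loading(self, geometry):
        # all force on the anterior-right sensor -> CoP at that corner
        forces = np.zeros((10, 4))
        forces[:, 1] = 500.0  # TR
        cop = board_cop(BoardForceTrace(forces=forces, fs=100.0), geometry)
        np.testing.assert_allclose(cop.ap, 433.0 / 2)
        np.testing.assert_allclose(cop.ml, 228.0 / 2)

    def test_matches_moment_balance_oracle(self, rng, geometry):
        trace = random_force_trace(rng)
        cop = board_cop(trace, geometry)
        # independent oracle: weighted centroid of the four sensor positions
        half_l, half_w = geometry.length_ap / 2, geometry.width_ml / 2
        pos = {  # (ap, ml) of TL, TR, BL, BR
            0: (half_l, -half_w),
            1: (half_l, half_w),
            2: (-half_l, -half_w),
            3: (-half_l, half_w),
        }
        for i in range(trace.n_samples):
            f = trace.forces[i]
            ap = sum(f[j] * pos[j][0] for j in range(4)) / f.sum()
            ml = sum(f[j] * pos[j][1] for j in range(4)) / f.sum()
            assert cop.ap[i] == pytest.approx(ap, abs=1e-9)
            assert cop.ml[i] == pytest.approx(ml, abs=1e-9)

    def test_cop_stays_inside_sensor_rectangle(self, rng, geometry):
        cop = board_cop(random_force_trace(rng, n=500), geometry)
        assert np.all(np.abs(cop.ap) <= geometry.length_ap / 2)
        assert np.all(np.abs(cop.ml) <= geometry.width_ml / 2)

    def test_scale_invariance(self, rng, geometry):
        trace = random_force_trace(rng)
        scaled = BoardForceTrace(forces=3.5 * trace.forces, fs=trace.fs)
        a, b = board_cop(trace, geometry), board_cop(scaled, geometry)
        np.testing.assert_allclose(a.ap, b.ap)
        np.testing.assert_allclose(a.ml, b.ml)

    def test_degenerate_load_names_sample(self, geometry):
        forces = np.full((20, 4), 50.0)
        forces[7] = 0.1
        with pytest.raises(DegenerateLoadError) as exc:
            board_cop(BoardForceTrace(forces=forces, fs=100.0), geometry)
        assert exc.value.sample_index == 7


def eight_sensor_oracle(left_trace, right_trace, left_geom, right_geom):
    """Single virtual plate over all 8 sensors at their global coordinates."""
    n = left_trace.n_samples
    ap_out, ml_out = np.empty(n), np.empty(n)
    for i in range(n):
        num_ap = num_ml = denom = 0.0
        for trace, geom in ((left_trace, left_geom), (right_trace, right_geom)):
            half_l, half_w = geom.length_ap / 2, geom.width_ml / 2
            pos = [
                (half_l, geom.origin_offset_ml - half_w),
                (half_l, geom.origin_offset_ml + half_w),
                (-half_l, geom.origin_offset_ml - half_w),
                (-half_l, geom.origin_offset_ml + half_w),
            ]
            for j, (ap_j, ml_j) in enumerate(pos):
                f = trace.forces[i, j]
                num_ap += f * ap_j
                num_ml += f * ml_j
                denom += f
        ap_out[i], ml_out[i] = num_ap / denom, num_ml / denom
    return ap_out, ml_out


class TestCombineBoards:
    def _setup(self, rng, left_scale=1.0, right_scale=1.0):
        lg = BoardGeometry(origin_offset_ml=-114.0)
        rg = BoardGeometry(origin_offset_ml=114.0)
        lt = random_force_trace(rng, base=200.0 * left_scale)
        rt = random_force_trace(rng, base=200.0 * right_scale)
        return lt, rt, lg, rg

    def test_all_weight_on_left_board(self, rng):
        lg = BoardGeometry(origin_offset_ml=-114.0)
        rg = BoardGeometry(origin_offset_ml=114.0)
        lt = random_force_trace(rng)
        cop_l = board_cop(lt, lg)
        zero = np.zeros(lt.n_samples)
        right = CoPTrace(ap=zero, ml=zero, fs=lt.fs)
        out = combine_boards(cop_l, lt.total_force(), right, zero, lg, rg)
        np.testing.assert_allclose(out.ap, cop_l.ap)
        np.testing.assert_allclose(out.ml, cop_l.ml + lg.origin_offset_ml)

    def test_symmetric_loading_centers(self):
        n, fs = 30, 100.0
        zero = np.zeros(n)
        w = np.full(n, 300.0)
        lg = BoardGeometry(origin_offset_ml=-80.0)
        rg = BoardGeometry(origin_offset_ml=80.0)
        out = combine_boards(
            CoPTrace(ap=zero, ml=zero, fs=fs), w,
            CoPTrace(ap=zero, ml=zero, fs=fs), w, lg, rg,
        )
        np.testing.assert_allclose(out.ap, 0.0, atol=1e-12)
        np.testing.assert_allclose(out.ml, 0.0, atol=1e-12)

    def test_matches_eight_sensor_oracle(self, rng):
        lt, rt, lg, rg = self._setup(rng, left_scale=1.4)
        out = combine_boards(
            board_cop(lt, lg), lt.total_force(),
            board_cop(rt, rg), rt.total_force(), lg, rg,
        )
        ap, ml = eight_sensor_oracle(lt, rt, lg, rg)
        np.testing.assert_allclose(out.ap, ap, atol=1e-9)
        np.testing.assert_allclose(out.ml, ml, atol=1e-9)

    def test_combined_cop_inside_hull(self, rng):
        lt, rt, lg, rg = self._setup(rng)
        out = combine_boards(
            board_cop(lt, lg), lt.total_force(),
            board_cop(rt, rg), rt.total_force(), lg, rg,
        )
        assert np.all(np.abs(out.ap) <= lg.length_ap / 2)
        assert np.all(np.abs(out.ml) <= rg.origin_offset_ml + rg.width_ml / 2)


class TestPreprocessTrial:
    def test_constant_forces_give_static_centroid(self):
        lf = np.tile([100.0, 120.0, 90.0, 110.0], (60, 1))
        rf = np.tile([80.0, 95.0, 85.0, 100.0], (60, 1))
        left = BoardForceTrace(forces=lf, fs=100.0)
        right = BoardForceTrace(forces=rf, fs=100.0)
        cop = preprocess_trial(left, right)
        ap, ml = eight_sensor_oracle(
            left, right,
            TrialConfig().left_geometry, TrialConfig().right_geometry,
        )
        np.testing.assert_allclose(cop.ap, ap, atol=1e-9)
        np.testing.assert_allclose(cop.ml, ml, atol=1e-9)

    def test_window_one_equals_unfiltered_pipeline(self, rng):
        left, right = random_force_trace(rng), random_force_trace(rng)
        cfg1 = TrialConfig(filter_window=1)
        out = preprocess_trial(left, right, cfg1)
        manual = combine_boards(
            board_cop(left, cfg1.left_geometry), left.total_force(),
            board_cop(right, cfg1.right_geometry), right.total_force(),
            cfg1.left_geometry, cfg1.right_geometry,
        )
        np.testing.assert_allclose(out.ap, manual.ap)
        np.testing.assert_allclose(out.ml, manual.ml)

    def test_sinusoidal_modulation_matches_staged_oracle(self, rng):
        # independent re-implementation of filter -> per-board CoP -> combine
        n, fs = 200, 100.0
        t = np.arange(n) / fs
        mod = 1.0 + 0.2 * np.sin(2 * np.pi * 0.7 * t)
        lf = np.column_stack([(100 + 10 * j) * mod for j in range(4)])
        rf = np.column_stack([(95 + 8 * j) * mod[::-1] for j in range(4)])
        cfg = TrialConfig(filter_window=15)
        out = preprocess_trial(
            BoardForceTrace(forces=lf, fs=fs), BoardForceTrace(forces=rf, fs=fs), cfg
        )

        def stage_filter(f):
            filt = np.empty_like(f)
            for j in range(4):
                for i in range(n):
                    h = min(7, i, n - 1 - i)
                    filt[i, j] = f[i - h : i + h + 1, j].mean()
            return filt

        lf_f, rf_f = stage_filter(lf), stage_filter(rf)
        ap, ml = eight_sensor_oracle(
            BoardForceTrace(forces=lf_f, fs=fs),
            BoardForceTrace(forces=rf_f, fs=fs),
            cfg.left_geometry, cfg.right_geometry,
        )
        np.testing.assert_allclose(out.ap, ap, atol=1e-9)
        np.testing.assert_allclose(out.ml, ml, atol=1e-9)

    def test_scaling_all_channels_leaves_cop_unchanged(self, rng):
        left, right = random_force_trace(rng), random_force_trace(rng)
        out = preprocess_trial(left, right)
        scaled = preprocess_trial(
            BoardForceTrace(forces=2.5 * left.forces, fs=left.fs),
            BoardForceTrace(forces=2.5 * right.forces, fs=right.fs),
        )
        np.testing.assert_allclose(out.ap, scaled.ap, atol=1e-9)
        np.testing.assert_allclose(out.ml, scaled.ml, atol=1e-9)


class TestForceTableIO:
    def test_roundtrip(self, rng, tmp_path):
        left, right = random_force_trace(rng), random_force_trace(rng)
        path = tmp_path / "trial.csv"
        write_force_table(path, left, right)
        left2, right2 = read_force_table(path)
        assert left2.fs == pytest.approx(100.0)
        np.testing.assert_allclose(left2.forces, left.forces, atol=1e-8)
        np.testing.assert_allclose(right2.forces, right.forces, atol=1e-8)

    def test_missing_column_rejected(self, rng, tmp_path):
        left, right = random_force_trace(rng), random_force_trace(rng)
        path = tmp_path / "trial.csv"
        write_force_table(path, left, right)
        import pandas as pd

        df = pd.read_csv(path).drop(columns=["R_BR"])
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="R_BR"):
            read_force_table(path)

    def test_config_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text(
            "filter_window: 9\nforce_floor: 2.0\n"
            "left_geometry: {length_ap: 400, width_ml: 200, origin_offset_ml: -100}\n"
        )
        cfg = TrialConfig.from_yaml(path)
        assert cfg.filter_window == 9
        assert cfg.force_floor == 2.0
        assert cfg.left_geometry.length_ap == 400
        assert cfg.right_geometry.origin_offset_ml == 114.0  # default kept
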