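"""Centroid, calibration, filtering, speed and the biological speed gate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tagtrax.kinematics import (
    ArenaSpec,
    Trajectory,
    apply_speed_gate,
    butterworth_smooth,
    calibrate,
    compute_centroid,
    compute_speed,
    interpolate_gaps,
)

from conftest import make_series, make_trajectory


class TestCentroid:
    def test_mean_of_square_is_center(self):
        series = make_series([[0.0, 0.0, 2.0, 2.0]], [[0.0, 2.0, 0.0, 2.0]])
        traj = compute_centroid(series, min_valid_landmarks=2)
        assert traj.x_mm[0] == 1.0 and traj.y_mm[0] == 1.0

    def test_partial_frame_uses_remaining_landmarks(self):
        x = np.array([[0.0, 0.0, 3.0, np.nan]])
        y = np.array([[0.0, 3.0, 0.0, np.nan]])
        series = make_series(x, y)
        traj = compute_centroid(series, min_valid_landmarks=2)
        assert traj.valid[0]
        assert traj.x_mm[0] == pytest.approx(1.0)

    def test_all_masked_frame_is_invalid(self):
        series = make_series([[np.nan, np.nan]], [[np.nan, np.nan]])
        traj = compute_centroid(series, min_valid_landmarks=1)
        assert not traj.valid[0]

    def test_antenna_landmarks_excluded(self):
        series = make_series([[1.0, 3.0, 100.0]], [[1.0, 3.0, 100.0]],
                             names=["head", "tail", "antenna_left"])
        traj = compute_centroid(series, min_valid_landmarks=1)
        assert traj.x_mm[0] == pytest.approx(2.0)

    def test_commutes_with_uniform_calibration(self, rng, arena):
        series = make_series(rng.uniform(0, 500, (30, 4)), rng.uniform(0, 500, (30, 4)))
        a = ArenaSpec(scale_x=0.25, scale_y=0.25, length_mm=200, width_mm=200)
        first = calibrate(compute_centroid(series, 2), a)
        scaled = make_series(series.x * 0.25, series.y * 0.25)
        second = compute_centroid(scaled, 2)
        np.testing.assert_allclose(first.x_mm, second.x_mm, atol=1e-9)


class TestCalibrate:
    def test_linear_map(self):
        traj = make_trajectory([100.0], [40.0])
        a = ArenaSpec(scale_x=0.25, scale_y=0.25)
        out = calibrate(traj, a)
        assert out.x_mm[0] == pytest.approx(25.0)
        assert out.y_mm[0] == pytest.approx(10.0)

    def test_identity_scales(self):
        traj = make_trajectory([12.0, 13.0], [7.0, 8.0])
        out = calibrate(traj, ArenaSpec(scale_x=1.0, scale_y=1.0))
        np.testing.assert_allclose(out.x_mm, traj.x_mm)

    def test_out_of_bounds_clamped(self):
        traj = make_trajectory([-3.0], [5.0])
        out = calibrate(traj, ArenaSpec(scale_x=1.0, scale_y=1.0))
        assert out.x_mm[0] == 0.0 and out.y_mm[0] == 5.0


class TestInterpolateGaps:
    def test_midpoint_fill(self):
        traj = make_trajectory([0.0, 99.0, 2.0], valid=[True, False, True])
        out = interpolate_gaps(traj, max_gap_frames=15)
        assert out.valid.all()
        assert out.x_mm[1] == pytest.approx(1.0)

    def test_long_gap_untouched(self):
        n = 20
        valid = np.ones(n, bool)
        valid[2:18] = False  # 16-frame gap
        traj = make_trajectory(np.arange(n, dtype=float), valid=valid)
        out = interpolate_gaps(traj, max_gap_frames=15)
        np.testing.assert_array_equal(out.valid, valid)

    def test_no_gaps_is_identity(self, rng):
        traj = make_trajectory(rng.uniform(0, 100, 50), rng.uniform(0, 50, 50))
        out = interpolate_gaps(traj)
        np.testing.assert_array_equal(out.x_mm, traj.x_mm)

    def test_leading_and_trailing_gaps_stay_invalid(self):
        traj = make_trajectory([1.0, 2.0, 3.0, 4.0], valid=[False, True, True, False])
        out = interpolate_gaps(traj, max_gap_frames=15)
        assert not out.valid[0] and not out.valid[3]


class TestButterworth:
    def test_dc_gain_is_unity(self):
        traj = make_trajectory(np.full(300, 5.0), np.full(300, 5.0))
        out = butterworth_smooth(traj, order=2, cutoff_hz=6)
        assert np.max(np.abs(out.x_mm - 5.0)) < 1e-6

    @pytest.mark.parametrize(
        "freq,expected,tol",
        [
            (6.0, 0.5, 0.01),      # zero-phase gain at the corner = (1/sqrt2)^2
            (1.0, 0.9985, 0.002),  # analytic |H|^2 at f/fc = 1/6
        ],
    )
    def test_sinusoid_amplitude_ratio(self, freq, expected, tol):
        fps = 30.0
        t = np.arange(6000) / fps
        x = 10.0 * np.sin(2 * np.pi * freq * t) + 50.0
        traj = make_trajectory(x, np.full_like(x, 40.0), fps=fps)
        out = butterworth_smooth(traj, order=2, cutoff_hz=6)
        mid = slice(1500, 4500)
        # project onto quadrature pair to measure steady-state amplitude
        basis = np.column_stack([np.sin(2 * np.pi * freq * t[mid]),
                                 np.cos(2 * np.pi * freq * t[mid])])
        coef, *_ = np.linalg.lstsq(basis, out.x_mm[mid] - 50.0, rcond=None)
        ratio = np.hypot(*coef) / 10.0
        assert ratio == pytest.approx(expected, abs=tol)

    def test_zero_phase_symmetric_pulse(self):
        n = 601
        t = np.arange(n)
        pulse = np.exp(-0.5 * ((t - 300) / 12.0) ** 2)
        traj = make_trajectory(pulse + 10.0, np.full(n, 5.0))
        out = butterworth_smooth(traj, order=2, cutoff_hz=6)
        assert np.max(np.abs(out.x_mm - out.x_mm[::-1])) < 1e-9

    def test_white_noise_variance_reduced_and_high_freq_attenuated(self, rng):
        x = rng.standard_normal(2048)
        traj = make_trajectory(x + 50.0, np.full(2048, 5.0))
        out = butterworth_smooth(traj)
        assert out.x_mm.var() < traj.x_mm.var()
        fin = np.abs(np.fft.rfft(x))
        fout = np.abs(np.fft.rfft(out.x_mm - 50.0))
        freqs = np.fft.rfftfreq(2048, 1 / 30.0)
        hi = freqs > 6.0
        assert fout[hi].sum() < 0.5 * fin[hi].sum()

    def test_cutoff_above_nyquist_rejected(self):
        traj = make_trajectory(np.zeros(100))
        with pytest.raises(ValueError, match="Nyquist"):
            butterworth_smooth(traj, cutoff_hz=15.0)

    def test_short_segments_pass_through(self):
        valid = np.array([True] * 5 + [False] * 20 + [True] * 100)
        x = np.arange(125, dtype=float)
        traj = make_trajectory(x, valid=valid)
        out = butterworth_smooth(traj)
        np.testing.assert_array_equal(out.x_mm[:5], x[:5])

    def test_invalid_frames_untouched(self, rng):
        valid = np.ones(200, bool)
        valid[40:80] = False
        x = rng.uniform(0, 100, 200)
        traj = make_trajectory(x.copy(), valid=valid)
        out = butterworth_smooth(traj)
        np.testing.assert_array_equal(out.x_mm[40:80], x[40:80])


class TestSpeed:
    def test_unit_displacement_at_30fps(self):
        traj = make_trajectory([0.0, 1.0], [0.0, 0.0])
        speeds = compute_speed(traj)
        assert speeds.speed_mm_s[0] == pytest.approx(30.0)

    def test_stationary_is_zero(self):
        traj = make_trajectory(np.full(10, 3.0), np.full(10, 4.0))
        assert np.all(compute_speed(traj).speed_mm_s == 0.0)

    def test_pythagorean_displacement(self):
        traj = make_trajectory([0.0, 3.0], [0.0, 4.0])
        assert compute_speed(traj).speed_mm_s[0] == pytest.approx(150.0)

    def test_interval_validity_requires_both_endpoints(self):
        traj = make_trajectory([0.0, 1.0, 2.0], valid=[True, False, True])
        speeds = compute_speed(traj)
        np.testing.assert_array_equal(speeds.valid, [False, False])


class TestSpeedGate:
    def test_fast_jump_invalidates_later_frame(self):
        traj = make_trajectory([0.0, 10.0, 10.5], [0.0, 0.0, 0.0])  # 300 mm/s jump
        speeds = compute_speed(traj)
        out = apply_speed_gate(traj, speeds, 230.0)
        np.testing.assert_array_equal(out.valid, [True, False, True])

    def test_slow_trajectory_unchanged(self):
        traj = make_trajectory(np.arange(10) * 0.1)
        out = apply_speed_gate(traj, compute_speed(traj), 230.0)
        assert out.valid.all()

    def test_exact_threshold_kept(self):
        step = 230.0 / 30.0
        traj = make_trajectory([0.0, step, 2 * step])
        out = apply_speed_gate(traj, compute_speed(traj), 230.0)
        assert out.valid.all()

    def test_first_frame_never_invalidated(self, rng):
        traj = make_trajectory(np.cumsum(rng.uniform(0, 20, 50)))
        out = apply_speed_gate(traj, compute_speed(traj), 230.0)
        assert out.valid[0]

    def test_noop_on_own_output_for_isolated_spikes(self, rng):
        """After removing isolated single-frame spikes, re-gating with
        recomputed speeds changes nothing."""
        x = np.cumsum(rng.uniform(0, 3, 80))
        x[20] += 15.0  # isolated spike: fast in, fast out
        traj = make_trajectory(x)
        once = apply_speed_gate(traj, compute_speed(traj), 230.0)
        assert not once.valid[20]
        twice = apply_speed_gate(once, compute_speed(once), 230.0)
        np.testing.assert_array_equal(once.valid, twice.valid)


@given(seed=st.integers(0, 2**16))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_chain_preserves_frame_count(seed):
    """Every stage returns as many frames as it was given."""
    r = np.random.default_rng(seed)
    n = int(r.integers(30, 200))
    valid = r.random(n) > 0.1
    traj = make_trajectory(r.uniform(0, 700, n), r.uniform(0, 300, n), valid=valid)
    arena = ArenaSpec(scale_x=0.25, scale_y=0.25)
    for stage in (
        lambda t: calibrate(t, arena),
        lambda t: interpolate_gaps(t, 15),
        lambda t: butterworth_smooth(t),
        lambda t: apply_speed_gate(t, compute_speed(t), 230.0),
    ):
        traj = stage(traj)
        assert traj.n_frames == n
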