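"""COP computation and target-error metric oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from posturekit.exceptions import (
    AlignmentError,
    EmptyTrajectoryError,
    MetricError,
    NoLandingError,
)
from posturekit.posturometrics import (
    balance_beam_error,
    combine_cop,
    compute_cop_single,
    detect_landing,
    one_leg_stand_error,
    precision_jump_error,
)
from posturekit.types import CopTrajectory, ForcePlateRecord, TaskGeometry


def _plate(fz, mx=None, my=None, fx=None, fy=None, **kw):
    n = len(fz)
    z = np.zeros(n)
    return ForcePlateRecord(
        fx=z if fx is None else fx,
        fy=z if fy is None else fy,
        fz=np.asarray(fz, float),
        mx=z if mx is None else mx,
        my=z if my is None else my,
        mz=z,
        **kw,
    )


def _traj(xy, rate=1000.0, valid=None, fz=None):
    xy = np.asarray(xy, float)
    if valid is None:
        valid = np.ones(len(xy), bool)
    return CopTrajectory(xy=xy, rate=rate, valid=valid, fz=fz)


class TestComputeCop:
    def test_centered_load_gives_origin(self):
        plate = _plate(np.full(100, 600.0))
        cop = compute_cop_single(plate)
        assert np.allclose(cop.xy, 0.0)
        assert cop.valid.all()

    def test_static_moment_balance(self):
        # COPx = -My/Fz, COPy = Mx/Fz with z0 = 0
        n = 50
        plate = _plate(np.full(n, 600.0), mx=np.full(n, 30.0), my=np.full(n, -15.0))
        cop = compute_cop_single(plate)
        assert np.allclose(cop.xy[:, 0], 25.0)
        assert np.allclose(cop.xy[:, 1], 50.0)

    def test_min_load_mask_matches_bruteforce(self):
        fz = np.linspace(0, 600, 200)
        plate = _plate(fz)
        cop = compute_cop_single(plate, min_load=10.0)
        assert np.array_equal(cop.valid, fz >= 10.0)

    def test_all_below_threshold_raises(self):
        plate = _plate(np.full(10, 1.0))
        with pytest.raises(EmptyTrajectoryError, match="minimum vertical load"):
            compute_cop_single(plate, min_load=10.0, label="S001 beam 1")

    def test_surface_offset_and_pose(self):
        # shear force with nonzero z0 shifts the COP; pose moves it to lab frame
        n = 10
        plate = _plate(
            np.full(n, 500.0),
            fx=np.full(n, 50.0),
            my=np.full(n, -10.0),
            z0=0.1,
            origin=np.array([1.0, 2.0, 0.0]),
        )
        cop = compute_cop_single(plate)
        # COPx = (10 - 50*0.1)/500 = 0.01 m plate frame -> 1.01 m lab = 1010 mm
        assert np.allclose(cop.xy[:, 0], 1010.0)
        assert np.allclose(cop.xy[:, 1], 2000.0)


class TestCombineCop:
    def test_one_side_invalid_reduces_to_other(self):
        left = _traj(np.tile([12.0, -4.0], (20, 1)))
        right = _traj(np.zeros((20, 2)), valid=np.zeros(20, bool))
        out = combine_cop(left, right)
        assert np.allclose(out.xy[out.valid], [12.0, -4.0])
        assert out.valid.all()
        assert out.provenance == "combined"

    def test_symmetric_average(self):
        left = _traj(np.tile([-100.0, 0.0], (10, 1)))
        right = _traj(np.tile([100.0, 0.0], (10, 1)))
        out = combine_cop(left, right)
        assert np.allclose(out.xy, 0.0)

    def test_force_weighted(self):
        n = 5
        left = _traj(np.tile([-100.0, 0.0], (n, 1)), fz=np.full(n, 400.0))
        right = _traj(np.tile([100.0, 0.0], (n, 1)), fz=np.full(n, 200.0))
        out = combine_cop(left, right, mode="force_weighted")
        assert np.allclose(out.xy[:, 0], -100 / 3, atol=1e-9)

    def test_mismatched_time_base_rejected(self):
        left = _traj(np.zeros((10, 2)))
        right = _traj(np.zeros((12, 2)))
        with pytest.raises(AlignmentError):
            combine_cop(left, right)


class TestBeamError:
    geometry = TaskGeometry()

    def test_on_centerline_is_zero(self):
        cop = _traj(np.column_stack([np.linspace(-1000, 1000, 50), np.zeros(50)]))
        assert balance_beam_error(cop, self.geometry).value == pytest.approx(0.0, abs=1e-9)

    def test_constant_offset(self):
        cop = _traj(np.column_stack([np.zeros(40), np.full(40, 12.0)]))
        assert balance_beam_error(cop, self.geometry).value == pytest.approx(12.0)

    def test_sinusoidal_deviation_closed_form(self):
        # mean |A sin| over whole periods = 2A/pi
        t = np.arange(20_000) / 1000.0
        amp = 9.0
        cop = _traj(np.column_stack([np.zeros_like(t), amp * np.sin(2 * np.pi * t)]))
        err = balance_beam_error(cop, self.geometry)
        assert err.value == pytest.approx(2 * amp / np.pi, rel=0.005)

    def test_no_valid_samples_raises(self):
        cop = _traj(np.zeros((5, 2)), valid=np.zeros(5, bool))
        with pytest.raises(MetricError):
            balance_beam_error(cop, self.geometry)


class TestOneLegStandError:
    def test_stationary_cop_zero(self):
        cop = _traj(np.tile([5.0, 5.0], (100, 1)))
        assert one_leg_stand_error(cop).value == 0.0

    def test_circle_radius(self):
        # whole revolutions: barycenter = center, mean distance = radius
        t = np.linspace(0, 4 * 2 * np.pi, 4000, endpoint=False)
        r = 8.0
        cop = _traj(np.column_stack([3 + r * np.cos(t), -2 + r * np.sin(t)]))
        assert one_leg_stand_error(cop).value == pytest.approx(r, abs=1e-6)

    def test_two_point_alternation(self):
        # equal time at (0,0) and (20,0): barycenter (10,0), mean distance 10
        xy = np.tile(np.array([[0.0, 0.0], [20.0, 0.0]]), (50, 1))
        assert one_leg_stand_error(_traj(xy)).value == pytest.approx(10.0)


class TestDetectLanding:
    def test_clean_step(self):
        fz = np.zeros(3000)
        fz[1200:] = 600.0
        t = detect_landing(_plate(fz), threshold=20.0, hold_ms=20.0)
        assert t == pytest.approx(1.200, abs=0.010)

    def test_never_loaded_raises(self):
        with pytest.raises(NoLandingError):
            detect_landing(_plate(np.full(500, 5.0)), threshold=20.0)

    def test_short_spike_rejected(self):
        fz = np.zeros(3000)
        fz[500:505] = 600.0  # 5 ms spike
        fz[2000:] = 600.0
        t = detect_landing(_plate(fz), threshold=20.0, hold_ms=20.0)
        assert t == pytest.approx(2.000, abs=0.010)


class TestPrecisionJumpError:
    geometry = TaskGeometry()

    def _toe(self, x, y, n=500):
        toe = np.zeros((n, 3))
        toe[:, 0] = x
        toe[:, 1] = y
        return toe

    def test_on_line_is_zero(self):
        err = precision_jump_error(self._toe(0.0, 0.0), 200.0, self.geometry, 1.0)
        assert err.value == 0.0

    def test_programmed_offset(self):
        err = precision_jump_error(self._toe(0.0, 35.0), 200.0, self.geometry, 1.0)
        assert err.value == pytest.approx(35.0)
        assert not err.meta["beyond_segment"]

    def test_beyond_segment_uses_endpoint_and_flags(self):
        # target segment spans x in [-300, 300]; land at (400, 30)
        err = precision_jump_error(self._toe(400.0, 30.0), 200.0, self.geometry, 1.0)
        assert err.value == pytest.approx(np.hypot(100.0, 30.0))
        assert err.meta["beyond_segment"]

    def test_nearest_valid_sample_within_window(self):
        toe = self._toe(0.0, 35.0)
        toe[198:203] = np.nan  # landing sample invalid, neighbors valid
        err = precision_jump_error(toe, 200.0, self.geometry, 1.0)
        assert err.value == pytest.approx(35.0)

    def test_no_valid_sample_near_landing_raises(self):
        toe = self._toe(0.0, 35.0)
        toe[150:250] = np.nan
        with pytest.raises(MetricError):
            precision_jump_error(toe, 200.0, self.geometry, 1.0)


@given(
    angle=st.floats(0, 2 * np.pi, allow_nan=False),
    dx=st.floats(-500, 500, allow_nan=False),
    dy=st.floats(-500, 500, allow_nan=False),
    seed=st.integers(0, 50),
)
def test_frame_invariance_of_metrics(angle, dx, dy, seed):
    """Rigid rotation+translation of all lab-frame inputs leaves errors unchanged."""
    rng = np.random.default_rng(seed)
    xy = rng.normal(0, 20, (200, 2))
    geometry = TaskGeometry()
    R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    shift = np.array([dx, dy])
    xy_t = xy @ R.T + shift
    geo_t = TaskGeometry(
        beam_line=geometry.beam_line @ R.T + shift,
        jump_target_line=geometry.jump_target_line @ R.T + shift,
    )
    e1 = balance_beam_error(_traj(xy), geometry).value
    e2 = balance_beam_error(_traj(xy_t), geo_t).value
    assert e2 == pytest.approx(e1, abs=1e-9 * max(1, abs(e1)))
    s1 = one_leg_stand_error(_traj(xy)).value
    s2 = one_leg_stand_error(_traj(xy_t)).value
    assert s2 == pytest.approx(s1, abs=1e-9 * max(1, abs(s1)))
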