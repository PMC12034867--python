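import numpy as np
import pytest
from hypothesis import given, strategies as st

from renalflow import digitize as dg
from renalflow import waveform_synth as ws
from renalflow.errors import CalibrationError, DataError, SignalQualityError


def identity_cal():
    return dg.AxisCalibration(x_refs=((0.0, 0.0), (1.0, 1.0)), y_refs=((0.0, 0.0), (1.0, 1.0)))


class TestCalibrate:
    def test_time_axis_midpoint(self):
        cal = dg.AxisCalibration(
            x_refs=((0.0, 0.0), (100.0, 1.0)), y_refs=((0.0, 0.0), (1.0, 1.0))
        )
        tx, _ = dg.calibrate(cal)
        assert tx(50.0) == pytest.approx(0.5)

    def test_inverted_velocity_axis(self):
        # image y grows downward: pixel 200 -> 0 cm/s, pixel 0 -> 100 cm/s
        cal = dg.AxisCalibration(
            x_refs=((0.0, 0.0), (1.0, 1.0)), y_refs=((200.0, 0.0), (0.0, 100.0))
        )
        _, ty = dg.calibrate(cal)
        assert ty(50.0) == pytest.approx(75.0)

    @given(
        a=st.floats(-5, 5).filter(lambda v: abs(v) > 1e-3),
        b=st.floats(-100, 100),
        p1=st.floats(-500, 500),
        dp=st.floats(1, 500),
    )
    def test_round_trips_random_generating_transform(self, a, b, p1, dp):
        p2 = p1 + dp
        cal = dg.AxisCalibration(
            x_refs=((p1, a * p1 + b), (p2, a * p2 + b)),
            y_refs=((0.0, 0.0), (1.0, 1.0)),
        )
        tx, _ = dg.calibrate(cal)
        assert tx.slope == pytest.approx(a, rel=1e-9, abs=1e-9)
        assert tx.intercept == pytest.approx(b, rel=1e-9, abs=1e-9)

    def test_coincident_reference_pixels_rejected(self):
        with pytest.raises(CalibrationError):
            dg.AxisCalibration(x_refs=((5.0, 0.0), (5.0, 1.0)), y_refs=((0.0, 0.0), (1.0, 1.0)))


class TestToPhysical:
    def test_identity_calibration_preserves_coordinates(self):
        pts = np.array([[0.0, 10.0], [1.0, 20.0], [2.0, 15.0]])
        trace = dg.to_physical(dg.PixelTrace(points=pts), identity_cal())
        np.testing.assert_allclose(trace.times, pts[:, 0])
        np.testing.assert_allclose(trace.velocities, pts[:, 1])

    def test_affine_map_preserves_collinearity(self):
        pts = np.array([[0.0, 0.0], [1.0, 2.0], [2.0, 4.0]])  # collinear
        cal = dg.AxisCalibration(
            x_refs=((0.0, 0.3), (10.0, 2.3)), y_refs=((0.0, 50.0), (100.0, -50.0))
        )
        trace = dg.to_physical(dg.PixelTrace(points=pts), cal)
        t, v = trace.times, trace.velocities
        cross = (t[1] - t[0]) * (v[2] - v[0]) - (t[2] - t[0]) * (v[1] - v[0])
        assert cross == pytest.approx(0.0, abs=1e-9)

    def test_duplicate_x_pixels_averaged(self):
        pts = np.array([[0.0, 10.0], [1.0, 20.0], [1.0, 30.0], [2.0, 40.0]])
        trace = dg.to_physical(dg.PixelTrace(points=pts), identity_cal())
        np.testing.assert_allclose(trace.times, [0.0, 1.0, 2.0])
        np.testing.assert_allclose(trace.velocities, [10.0, 25.0, 40.0])

    def test_reversed_time_axis_is_an_error(self):
        pts = np.array([[0.0, 1.0], [1.0, 2.0]])
        cal = dg.AxisCalibration(
            x_refs=((0.0, 1.0), (1.0, 0.0)), y_refs=((0.0, 0.0), (1.0, 1.0))
        )  # negative slope reverses time order
        with pytest.raises(DataError, match="monotone"):
            dg.to_physical(dg.PixelTrace(points=pts), cal)

    def test_uniform_pixel_rescaling_invariance(self):
        pts = np.array([[10.0, 100.0], [20.0, 60.0], [35.0, 80.0]])
        cal = dg.AxisCalibration(
            x_refs=((10.0, 0.0), (35.0, 1.0)), y_refs=((100.0, 0.0), (0.0, 120.0))
        )
        scaled_cal = dg.AxisCalibration(
            x_refs=((30.0, 0.0), (105.0, 1.0)), y_refs=((300.0, 0.0), (0.0, 120.0))
        )
        a = dg.to_physical(dg.PixelTrace(points=pts), cal)
        b = dg.to_physical(dg.PixelTrace(points=pts * 3.0), scaled_cal)
        np.testing.assert_allclose(a.times, b.times, atol=1e-12)
        np.testing.assert_allclose(a.velocities, b.velocities, atol=1e-12)


class TestExtractBeat:
    def _beat_trace(self, seed=0):
        params = ws.WaveformParams(psv=110.0, edv=25.0, accel_time=0.05, heart_period=0.8)
        return ws.render_beat(params), params

    def test_single_beat_returned_unchanged(self):
        trace, _ = self._beat_trace()
        out = dg.extract_beat(trace)
        assert len(out) == len(trace)

    def test_first_of_two_concatenated_beats_isolated(self):
        trace, params = self._beat_trace()
        t2 = np.concatenate([trace.times, trace.times + params.heart_period])
        v2 = np.concatenate([trace.velocities, trace.velocities])
        out = dg.extract_beat(dg.CalibratedTrace(times=t2, velocities=v2))
        assert abs(len(out) - len(trace)) <= 1

    def test_flat_trace_raises_signal_quality_error(self):
        t = np.linspace(0, 1, 100)
        with pytest.raises(SignalQualityError):
            dg.extract_beat(dg.CalibratedTrace(times=t, velocities=np.full(100, 42.0)))


class TestResampleToGrid:
    def test_grid_constants(self):
        assert dg.TIME_GRID.shape == (1000,)
        assert dg.TIME_GRID[0] == pytest.approx(0.1)
        assert dg.TIME_GRID[-1] == pytest.approx(2.5)
        steps = np.diff(dg.TIME_GRID)
        np.testing.assert_allclose(steps, 2.4 / 999, rtol=1e-12)

    def test_linear_trace_reproduced_exactly(self):
        trace = dg.CalibratedTrace(times=np.array([0.1, 2.5]), velocities=np.array([0.0, 100.0]))
        sig = dg.resample_to_grid(trace, label="normal", patient_id="P", site="distal")
        expected = (dg.TIME_GRID - 0.1) / 2.4 * 100.0
        np.testing.assert_allclose(sig.velocities, expected, atol=1e-12)

    def test_constant_trace_fills_grid(self):
        trace = dg.CalibratedTrace(times=np.array([0.0, 0.7]), velocities=np.array([50.0, 50.0]))
        sig = dg.resample_to_grid(trace, label="normal", patient_id="P", site="distal")
        np.testing.assert_allclose(sig.velocities, 50.0)

    def test_matches_bruteforce_two_point_interpolation(self):
        # independent oracle: explicit two-point interpolation at every grid point
        knot_t = np.array([0.1, 0.35, 0.8, 1.4, 2.0])
        knot_v = np.array([10.0, 90.0, 30.0, 55.0, 20.0])
        trace = dg.CalibratedTrace(times=knot_t, velocities=knot_v)
        sig = dg.resample_to_grid(trace, label="ARAS", patient_id="P", site="origin")
        for g, got in zip(dg.TIME_GRID, sig.velocities):
            if g >= knot_t[-1]:
                expected = knot_v[-1]
            else:
                j = np.searchsorted(knot_t, g, side="right") - 1
                t0, t1 = knot_t[j], knot_t[j + 1]
                w = (g - t0) / (t1 - t0)
                expected = (1 - w) * knot_v[j] + w * knot_v[j + 1]
            assert abs(got - expected) <= 1e-12

    def test_singleton_trace_rejected(self):
        trace = dg.CalibratedTrace(times=np.array([0.5]), velocities=np.array([10.0]))
        with pytest.raises(DataError):
            dg.resample_to_grid(trace, label="normal", patient_id="P", site="distal")

    def test_round_trip_against_analytic_envelope(self):
        # synthesize -> render at 2 ms -> resample; compare with the analytic
        # envelope at grid times, within the linear-interpolation error bound
        # max|f''| * dt^2 / 8 estimated by finite differences
        params = ws.WaveformParams(psv=100.0, edv=20.0, accel_time=0.05, heart_period=0.8)
        trace = ws.render_beat(params)
        sig = dg.resample_to_grid(trace, label="normal", patient_id="P", site="middle")
        tt = np.linspace(0, params.heart_period, 40_000, endpoint=False)
        vv = ws.beat_envelope(params, tt)
        d2 = np.abs(np.diff(vv, 2)) / (tt[1] - tt[0]) ** 2
        bound = d2.max() * ws.RENDER_DT**2 / 8 + 1e-9
        in_beat = dg.TIME_GRID - 0.1 < trace.times[-1]
        direct = ws.beat_envelope(params, np.clip(dg.TIME_GRID - 0.1, 0, params.heart_period * 0.999999))
        err = np.abs(sig.velocities[in_beat] - direct[in_beat])
        assert err.max() <= bound
        # clamp region holds the final traced velocity
        assert np.all(sig.velocities[~in_beat] == trace.velocities[-1])


class TestFileIO:
    def test_trace_and_calibration_round_trip(self, tmp_path):
        trace_file = tmp_path / "trace.csv"
        trace_file.write_text("x_px,y_px\n0,200\n10,120\n20,160\n")
        cal_file = tmp_path / "cal.csv"
        cal_file.write_text(
            "axis,pixel,value\nx,0,0.0\nx,20,1.0\ny,200,0.0\ny,0,100.0\n"
        )
        trace = dg.read_trace_csv(trace_file)
        cal = dg.read_calibration_csv(cal_file)
        phys = dg.to_physical(trace, cal)
        np.testing.assert_allclose(phys.times, [0.0, 0.5, 1.0])
        np.testing.assert_allclose(phys.velocities, [0.0, 40.0, 20.0])

    def test_missing_columns_reported(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("x,y\n1,2\n")
        with pytest.raises(DataError, match="x_px"):
            dg.read_trace_csv(bad)
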