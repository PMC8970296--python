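"""Tracking tests: likelihood fill, kinematics, tortuosity, metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mini2p_tuning.tracking import (TrackingSeries, fill_low_likelihood,
                                    head_kinematics, moving_average,
                                    openfield_metrics, tortuosity)

FR = 15.0


def _table(parts_xy, likelihood=None):
    """Build a long-format table from {part: (x_array, y_array)}."""
    rows = []
    n = len(next(iter(parts_xy.values()))[0])
    for part, (x, y) in parts_xy.items():
        lk = np.ones(n) if likelihood is None else likelihood[part]
        rows.append(pd.DataFrame({"frame": np.arange(n), "part": part,
                                  "x": x, "y": y, "likelihood": lk}))
    return pd.concat(rows, ignore_index=True)


def _straight_table(n, step=1.0):
    x = np.arange(n, dtype=float) * step
    zeros = np.zeros(n)
    return _table({
        "left_ear": (x, zeros + 1.0),
        "right_ear": (x, zeros - 1.0),
        "body_center": (x - 2.0, zeros),
        "tail_base": (x - 4.0, zeros),
    })


class TestFill:
    def test_all_good_unchanged(self):
        t = _straight_table(10)
        out = fill_low_likelihood(t)
        pd.testing.assert_frame_equal(
            out.sort_values(["frame", "part"]).reset_index(drop=True),
            t.sort_values(["frame", "part"]).reset_index(drop=True))

    def test_single_flagged_neighbor_mean(self):
        n = 11
        x = np.arange(n, dtype=float) * 2
        x[5] = 999.0
        lk = {p: np.ones(n) for p in ("left_ear", "right_ear", "body_center",
                                      "tail_base")}
        lk["left_ear"][5] = 0.2
        t = _table({"left_ear": (x, np.zeros(n)),
                    "right_ear": (x, np.zeros(n)),
                    "body_center": (x, np.zeros(n)),
                    "tail_base": (x, np.zeros(n))}, lk)
        out = fill_low_likelihood(t)
        le = out[out["part"] == "left_ear"].sort_values("frame")
        assert le["x"].iloc[5] == pytest.approx((8.0 + 12.0) / 2)

    def test_boundary_copies_single_neighbor(self):
        n = 5
        x = np.arange(n, dtype=float)
        lk = {p: np.ones(n) for p in ("left_ear", "right_ear", "body_center",
                                      "tail_base")}
        lk["left_ear"][0] = 0.1
        t = _table({p: (x.copy(), np.zeros(n)) for p in lk}, lk)
        out = fill_low_likelihood(t)
        le = out[out["part"] == "left_ear"].sort_values("frame")
        assert le["x"].iloc[0] == le["x"].iloc[1]

    def test_consecutive_run_outside_in(self):
        n = 7
        x = np.array([0.0, 10.0, 99.0, 99.0, 99.0, 50.0, 60.0])
        lk = {p: np.ones(n) for p in ("left_ear", "right_ear", "body_center",
                                      "tail_base")}
        lk["left_ear"][[2, 3, 4]] = 0.0
        t = _table({p: (x.copy(), np.zeros(n)) for p in lk}, lk)
        out = fill_low_likelihood(t)
        le = out[out["part"] == "left_ear"].sort_values("frame")["x"].to_numpy()
        # outer frames filled from real neighbours first, middle from those
        assert le[2] != 99.0 and le[3] != 99.0 and le[4] != 99.0
        assert 10.0 <= le[2] <= 50.0


class TestKinematics:
    def test_head_midpoint_and_direction(self):
        n = 5
        t = _table({
            "left_ear": (np.zeros(n), np.zeros(n)),
            "right_ear": (np.full(n, 2.0), np.zeros(n)),
            "body_center": (np.ones(n), np.zeros(n)),
            "tail_base": (np.ones(n), np.zeros(n)),
        })
        tr = head_kinematics(t, FR)
        assert np.allclose(tr.x, 1.0)
        assert np.allclose(tr.y, 0.0)
        assert np.allclose(tr.direction, 90.0)

    def test_stationary_zero_speed(self):
        t = _straight_table(10, step=0.0)
        tr = head_kinematics(t, FR)
        assert np.allclose(tr.speed, 0.0)

    def test_three_point_regression_equals_mean(self):
        # closed-form: a centred linear fit evaluated at the centre = mean
        rng = np.random.default_rng(0)
        n = 50
        y = rng.normal(size=n)
        t = _table({
            "left_ear": (y, np.ones(n)),
            "right_ear": (y, -np.ones(n)),
            "body_center": (y, np.zeros(n)),
            "tail_base": (y, np.zeros(n)),
        })
        tr = head_kinematics(t, FR)
        expect = np.convolve(y, np.ones(3) / 3, mode="valid")
        assert np.allclose(tr.x[1:-1], expect)

    def test_coincident_ears_nan_direction(self):
        n = 4
        t = _table({p: (np.zeros(n), np.zeros(n))
                    for p in ("left_ear", "right_ear", "body_center", "tail_base")})
        tr = head_kinematics(t, FR)
        assert np.isnan(tr.direction).all()


class TestTortuosity:
    def test_straight_line_unity(self):
        n = 200
        tr = TrackingSeries(x=np.arange(n, dtype=float), y=np.zeros(n),
                            speed=np.full(n, FR), direction=np.zeros(n),
                            frame_rate_hz=FR)
        T = tortuosity(tr)
        mid = T[np.isfinite(T)]
        assert np.allclose(mid, 1.0, atol=1e-9)

    def test_semicircle_pi_over_two(self):
        # constant-speed semicircular arc spanning exactly the +/-1.25 s window
        fr = 40.0
        half_w = int(round(1.25 * fr))
        n = 2 * half_w + 1
        th = np.linspace(0, np.pi, n)
        r = 30.0
        tr = TrackingSeries(x=r * np.cos(th), y=r * np.sin(th),
                            speed=np.zeros(n), direction=np.zeros(n),
                            frame_rate_hz=fr)
        T = tortuosity(tr, position_smooth_s=0.0)
        assert T[half_w] == pytest.approx(np.pi / 2, abs=0.01)

    def test_right_angle_sqrt_two(self):
        fr = 4.0
        half_w = int(round(1.25 * fr))  # 5 steps per side
        xs = np.concatenate([np.linspace(0, 1, half_w + 1),
                             np.ones(half_w)])
        ys = np.concatenate([np.zeros(half_w + 1),
                             np.linspace(0, 1, half_w + 1)[1:]])
        n = len(xs)
        tr = TrackingSeries(x=xs, y=ys, speed=np.zeros(n),
                            direction=np.zeros(n), frame_rate_hz=fr)
        T = tortuosity(tr, position_smooth_s=0.0)
        assert T[half_w] == pytest.approx(np.sqrt(2), abs=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_at_least_one_where_defined(self, seed):
        rng = np.random.default_rng(seed)
        n = 120
        x = np.cumsum(rng.normal(size=n))
        y = np.cumsum(rng.normal(size=n))
        tr = TrackingSeries(x=x, y=y, speed=np.zeros(n),
                            direction=np.zeros(n), frame_rate_hz=FR)
        T = tortuosity(tr)
        assert np.all(T[np.isfinite(T)] >= 1.0 - 1e-12)


class TestIsometryInvariance:
    def test_rotation_translation(self):
        rng = np.random.default_rng(1)
        n = 400
        x = np.cumsum(rng.normal(size=n)) + 40
        y = np.cumsum(rng.normal(size=n)) + 40
        base = TrackingSeries(x=x, y=y, speed=np.concatenate(
            [[0], np.hypot(np.diff(x), np.diff(y)) * FR]),
            direction=np.full(n, 10.0), frame_rate_hz=FR)
        phi = np.radians(30.0)
        xr = np.cos(phi) * x - np.sin(phi) * y + 5.0
        yr = np.sin(phi) * x + np.cos(phi) * y - 3.0
        rot = TrackingSeries(x=xr, y=yr, speed=np.concatenate(
            [[0], np.hypot(np.diff(xr), np.diff(yr)) * FR]),
            direction=np.full(n, 40.0), frame_rate_hz=FR)
        assert np.allclose(base.speed, rot.speed, atol=1e-9)
        Ta, Tb = tortuosity(base), tortuosity(rot)
        assert np.allclose(Ta[np.isfinite(Ta)], Tb[np.isfinite(Tb)], atol=1e-9)


class TestOpenFieldMetrics:
    def test_stationary_all_zero(self):
        n = 150
        tr = TrackingSeries(x=np.full(n, 40.0), y=np.full(n, 40.0),
                            speed=np.zeros(n), direction=np.zeros(n),
                            frame_rate_hz=FR)
        m = openfield_metrics(tr, 80.0)
        assert m.total_distance_cm == 0.0
        # central start position: whole session counts as centre time
        assert m.center_time_s == pytest.approx(n / FR)

    def test_constant_speed_arithmetic(self):
        # 10 cm/s for 60 s: 600 cm, median = p90 = 10
        n = int(60 * FR) + 1
        x = np.arange(n) * (10.0 / FR)
        tr = TrackingSeries(x=x, y=np.zeros(n), speed=np.full(n, 10.0),
                            direction=np.zeros(n), frame_rate_hz=FR)
        m = openfield_metrics(tr, 2 * x.max(), position_smooth_s=0.0)
        assert m.total_distance_cm == pytest.approx(600.0, rel=1e-6)
        assert m.median_speed_cm_s == pytest.approx(10.0, rel=1e-6)
        assert m.p90_speed_cm_s == pytest.approx(10.0, rel=1e-6)

    def test_accumulated_distance_nondecreasing(self):
        rng = np.random.default_rng(2)
        n = 300
        tr = TrackingSeries(x=np.cumsum(rng.normal(size=n)),
                            y=np.cumsum(rng.normal(size=n)),
                            speed=np.zeros(n), direction=np.zeros(n),
                            frame_rate_hz=FR)
        m = openfield_metrics(tr, 80.0)
        assert np.all(np.diff(m.accumulated_distance_cm) >= -1e-12)


class TestMovingAverage:
    def test_constant_preserved(self):
        assert np.allclose(moving_average(np.full(20, 3.0), FR), 3.0)
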