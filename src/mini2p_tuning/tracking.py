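"""Behavioural tracking: body-part tables to head kinematics and path metrics.

Pose estimation yields, per video frame, pixel coordinates and a confidence
("likelihood") for four body parts: left ear, right ear, body centre and tail
base.  This module turns those tables into head position (ear midpoint),
running speed, head direction (90 degrees anticlockwise from the left-ear to
right-ear vector), path tortuosity, and the open-field behaviour metrics used
to compare session-level mobility.

Arena coordinates are mathematical (y up).  Tables coming from image pixels
(y down) must be flipped on ingestion; see :func:`flip_image_y`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BODY_PARTS = ("left_ear", "right_ear", "body_center", "tail_base")


@dataclass
class TrackingSeries:
    """Per-frame head kinematics in arena coordinates (cm, cm/s, degrees)."""

    x: np.ndarray
    y: np.ndarray
    speed: np.ndarray
    direction: np.ndarray  # degrees in [0, 360); NaN where undefined
    frame_rate_hz: float
    tortuosity: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return len(self.x)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz


def flip_image_y(table: pd.DataFrame, height_px: float) -> pd.DataFrame:
    """Convert an image-pixel table (y down) to arena convention (y up)."""
    out = table.copy()
    out["y"] = height_px - out["y"]
    return out


def fill_low_likelihood(table: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Replace low-confidence coordinates by the mean of neighbouring frames.

    Frames whose likelihood falls below ``threshold`` get their x/y replaced
    by the mean of the immediately preceding and following frame.  Runs of
    consecutive flagged frames are resolved iteratively from the outside in,
    using already-filled values; a flagged frame at a session boundary copies
    its single existing neighbour.
    """
    out = table.sort_values(["part", "frame"]).reset_index(drop=True)
    for part, idx in out.groupby("part").groups.items():
        sub = out.loc[idx]
        x = sub["x"].to_numpy(dtype=float).copy()
        y = sub["y"].to_numpy(dtype=float).copy()
        bad = sub["likelihood"].to_numpy(dtype=float) < threshold
        _fill_runs(x, bad)
        _fill_runs(y, bad)
        out.loc[idx, "x"] = x
        out.loc[idx, "y"] = y
    return out.sort_values(["frame", "part"]).reset_index(drop=True)


def _fill_runs(v: np.ndarray, bad: np.ndarray) -> None:
    """In-place outside-in fill of flagged entries.

    Each pass fills every flagged frame that has at least one resolved
    neighbour with the mean of its resolved neighbours (a single neighbour at
    a run edge or session boundary is copied); runs therefore resolve from
    the outside in, reusing already-filled values.
    """
    n = len(v)
    remaining = bad.copy()
    while remaining.any():
        snapshot = remaining.copy()
        progressed = False
        for i in np.flatnonzero(snapshot):
            vals = []
            if i > 0 and not snapshot[i - 1]:
                vals.append(v[i - 1])
            if i < n - 1 and not snapshot[i + 1]:
                vals.append(v[i + 1])
            if vals:
                v[i] = float(np.mean(vals))
                remaining[i] = False
                progressed = True
        if not progressed:
            # whole-session run: nothing trustworthy to copy from
            break


def _regression_smooth(v: np.ndarray, frame_rate_hz: float, window_s: float = 0.2) -> np.ndarray:
    """Centred linear-regression smoothing, window of ``window_s`` seconds.

    For a symmetric window the fitted value at the centre frame equals the
    window mean; edge frames use a truncated window and an explicit
    least-squares fit evaluated at the centre frame.
    """
    n = len(v)
    w = max(3, int(round(window_s * frame_rate_hz)))
    if w % 2 == 0:
        w += 1
    k = w // 2
    out = np.empty(n)
    if n > 2 * k:
        kernel = np.full(2 * k + 1, 1.0 / (2 * k + 1))
        out[k:n - k] = np.convolve(v, kernel, mode="valid")
    for i in list(range(min(k, n))) + list(range(max(n - k, 0), n)):
        lo, hi = max(0, i - k), min(n, i + k + 1)
        t = np.arange(lo, hi, dtype=float)
        seg = v[lo:hi]
        if len(seg) < 2:
            out[i] = seg[0]
            continue
        b, a = np.polyfit(t, seg, 1)
        out[i] = a + b * i
    return out


def head_kinematics(
    table: pd.DataFrame,
    frame_rate_hz: float,
    pixel_size_cm: float = 1.0,
    smooth_window_s: float = 0.2,
) -> TrackingSeries:
    """Derive head position, speed and head direction from a filled table.

    Head position is the midpoint of the two ears, smoothed by independent
    centred linear-regression windows; speed is the inter-frame step length
    divided by the frame interval; head direction is 90 degrees anticlockwise
    to the left-ear-to-right-ear vector.  Coincident ears yield NaN direction
    for that frame.
    """
    wide = table.pivot_table(index="frame", columns="part", values=["x", "y"], sort=True)
    lx = wide[("x", "left_ear")].to_numpy() * pixel_size_cm
    ly = wide[("y", "left_ear")].to_numpy() * pixel_size_cm
    rx = wide[("x", "right_ear")].to_numpy() * pixel_size_cm
    ry = wide[("y", "right_ear")].to_numpy() * pixel_size_cm

    hx = _regression_smooth(0.5 * (lx + rx), frame_rate_hz, smooth_window_s)
    hy = _regression_smooth(0.5 * (ly + ry), frame_rate_hz, smooth_window_s)

    step = np.hypot(np.diff(hx), np.diff(hy))
    speed = np.concatenate([[0.0], step * frame_rate_hz])

    dx, dy = rx - lx, ry - ly
    with np.errstate(invalid="ignore"):
        direction = (np.degrees(np.arctan2(dy, dx)) + 90.0) % 360.0
    direction[np.hypot(dx, dy) < 1e-12] = np.nan

    return TrackingSeries(x=hx, y=hy, speed=speed, direction=direction,
                          frame_rate_hz=frame_rate_hz)


def moving_average(v: np.ndarray, frame_rate_hz: float, window_s: float = 0.5) -> np.ndarray:
    """Truncated (edge-renormalised) moving average over ``window_s``."""
    w = max(1, int(round(window_s * frame_rate_hz)))
    kernel = np.ones(w)
    num = np.convolve(v, kernel, mode="same")
    den = np.convolve(np.ones_like(v), kernel, mode="same")
    return num / den


def tortuosity(
    series: TrackingSeries,
    half_window_s: float = 1.25,
    position_smooth_s: float = 0.5,
    chord_tol_cm: float = 1e-9,
) -> np.ndarray:
    """Path-length over chord-length ratio in a sliding +/- window.

    Positions are first smoothed with a short moving average; the ratio is
    L(t)/D(t) where L sums inter-frame distances over [t-hw, t+hw] and D is
    the straight-line distance between the window ends.  NaN where the window
    is incomplete (session edges) or the chord is below tolerance.
    """
    x = moving_average(series.x, series.frame_rate_hz, position_smooth_s)
    y = moving_average(series.y, series.frame_rate_hz, position_smooth_s)
    n = len(x)
    hw = int(round(half_window_s * series.frame_rate_hz))
    d = np.hypot(np.diff(x), np.diff(y))
    cum = np.concatenate([[0.0], np.cumsum(d)])  # cum[i] = path length to frame i
    T = np.full(n, np.nan)
    idx = np.arange(hw, n - hw)
    if len(idx) == 0:
        return T
    L = cum[idx + hw] - cum[idx - hw]
    D = np.hypot(x[idx + hw] - x[idx - hw], y[idx + hw] - y[idx - hw])
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = L / D
    vals[D < chord_tol_cm] = np.nan
    T[idx] = vals
    return T


@dataclass
class OpenFieldMetrics:
    """Session-level mobility summary for a square open-field arena."""

    accumulated_distance_cm: np.ndarray
    total_distance_cm: float
    median_speed_cm_s: float
    p90_speed_cm_s: float
    center_time_s: float
    center_distance_cm: float
    tortuosity_p50: float
    tortuosity_p75: float
    turning_time_s: float
    turning_speed_p50: float
    turning_speed_p75: float


def openfield_metrics(
    series: TrackingSeries,
    arena_width_cm: float,
    arena_height_cm: float | None = None,
    center_halfwidth_cm: float = 15.0,
    position_smooth_s: float = 0.5,
    tortuosity_threshold: float = 1.96,
    running_speed_threshold: float = 7.3,
    turning_speed_floor: float = 2.5,
) -> OpenFieldMetrics:
    """Open-field behaviour metrics from a tracking series.

    Distances use positions smoothed with a 0.5-s moving average.  The centre
    region is the square within ``center_halfwidth_cm`` of the arena centre in
    both axes.  Tortuosity percentiles are taken over running frames (speed
    above ``running_speed_threshold``); turning metrics over frames with
    tortuosity above ``tortuosity_threshold`` while moving faster than
    ``turning_speed_floor``.  The two thresholds were calibrated on unimpeded
    control sessions and enter as parameters.
    """
    if arena_height_cm is None:
        arena_height_cm = arena_width_cm
    fr = series.frame_rate_hz
    x = moving_average(series.x, fr, position_smooth_s)
    y = moving_average(series.y, fr, position_smooth_s)
    d = np.hypot(np.diff(x), np.diff(y))
    accum = np.concatenate([[0.0], np.cumsum(d)])
    step_speed = np.concatenate([[0.0], d * fr])

    cx, cy = arena_width_cm / 2.0, arena_height_cm / 2.0
    in_center = (np.abs(x - cx) <= center_halfwidth_cm) & (np.abs(y - cy) <= center_halfwidth_cm)
    center_time = float(np.sum(in_center)) / fr
    center_distance = float(np.sum(d[in_center[1:]]))

    T = series.tortuosity if series.tortuosity is not None else tortuosity(series)
    running = step_speed > running_speed_threshold
    run_T = T[running & np.isfinite(T)]
    t50 = float(np.percentile(run_T, 50)) if len(run_T) else float("nan")
    t75 = float(np.percentile(run_T, 75)) if len(run_T) else float("nan")

    turning = np.isfinite(T) & (T > tortuosity_threshold) & (step_speed > turning_speed_floor)
    turn_speed = step_speed[turning]
    s50 = float(np.percentile(turn_speed, 50)) if len(turn_speed) else float("nan")
    s75 = float(np.percentile(turn_speed, 75)) if len(turn_speed) else float("nan")

    return OpenFieldMetrics(
        accumulated_distance_cm=accum,
        total_distance_cm=float(accum[-1]),
        median_speed_cm_s=float(np.median(step_speed)),
        p90_speed_cm_s=float(np.percentile(step_speed, 90)),
        center_time_s=center_time,
        center_distance_cm=center_distance,
        tortuosity_p50=t50,
        tortuosity_p75=t75,
        turning_time_s=float(np.sum(turning)) / fr,
        turning_speed_p50=s50,
        turning_speed_p75=s75,
    )
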