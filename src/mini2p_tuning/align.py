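"""Align multi-plane activity to tracking frames; cell eligibility.

With X interleaved imaging planes each cell's activity holds 1/X of the
tracking frames: plane p's sample k corresponds to tracking frame k*X + p
(0-based).  Tail tracking frames not divisible by X are dropped from the
pairing.  Eligibility for tuning analysis requires SNR > 3 and strictly more
than 100 calcium events.
"""

from __future__ import annotations

import numpy as np

from .tracking import TrackingSeries


def plane_indices(n_tracking_frames: int, n_planes: int) -> list:
    """Tracking-frame index sets per plane (disjoint partition, tail dropped)."""
    if n_planes < 1:
        raise ValueError("n_planes must be at least 1")
    usable = n_tracking_frames - n_tracking_frames % n_planes
    return [np.arange(p, usable, n_planes) for p in range(n_planes)]


def align_planes(
    activity_len: int,
    tracking: TrackingSeries,
    plane: int,
    n_planes: int,
) -> tuple[np.ndarray, TrackingSeries]:
    """Pair one plane's activity samples with its tracking subsequence.

    Returns (tracking_frame_indices, tracking subsequence at the per-plane
    stack rate).  A mismatch beyond one frame between the activity length
    and the plane subsequence is an error; a single tail frame is trimmed.
    """
    idx = plane_indices(tracking.n_frames, n_planes)[plane]
    if abs(len(idx) - activity_len) > 1:
        raise ValueError(
            f"activity length {activity_len} does not match plane subsequence "
            f"length {len(idx)}")
    n = min(len(idx), activity_len)
    idx = idx[:n]
    sub = TrackingSeries(
        x=tracking.x[idx], y=tracking.y[idx], speed=tracking.speed[idx],
        direction=tracking.direction[idx],
        frame_rate_hz=tracking.frame_rate_hz / n_planes,
        tortuosity=None if tracking.tortuosity is None else tracking.tortuosity[idx],
    )
    return idx, sub


def eligibility(snr: float, n_events: int, snr_min: float = 3.0,
                events_min: int = 100) -> dict:
    """Strict eligibility gates for tuning analysis."""
    snr_ok = bool(snr > snr_min)
    events_ok = bool(n_events > events_min)
    return {"snr_ok": snr_ok, "events_ok": events_ok,
            "eligible": snr_ok and events_ok}
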