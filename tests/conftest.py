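"""Shared fixtures: seeded synthetic sessions reused across test modules."""

import numpy as np
import pytest

from mini2p_tuning.classify import SessionContext
from mini2p_tuning.synthetic import ArenaSpec, Mobility, simulate_trajectory
from mini2p_tuning.tracking import head_kinematics


@pytest.fixture(scope="session")
def arena_30min():
    return ArenaSpec(width_cm=80.0, height_cm=80.0, frame_rate_hz=15.0,
                     duration_s=1800.0)


@pytest.fixture(scope="session")
def tracking_30min(arena_30min):
    table = simulate_trajectory(arena_30min, Mobility(), seed=42)
    return head_kinematics(table, arena_30min.frame_rate_hz)


@pytest.fixture(scope="session")
def context_30min(arena_30min, tracking_30min):
    tr = tracking_30min
    return SessionContext(
        x=tr.x, y=tr.y, speed=tr.speed, direction=tr.direction,
        frame_rate_hz=arena_30min.frame_rate_hz,
        extent_cm=(arena_30min.width_cm, arena_30min.height_cm))


def events_from_rate(rate_hz, frame_rate_hz, seed):
    """Per-frame event-amplitude series drawn from a rate model."""
    from mini2p_tuning.synthetic import draw_events

    frames, amps = draw_events(rate_hz, frame_rate_hz, seed=seed)
    ev = np.zeros(len(rate_hz))
    np.add.at(ev, frames, amps)
    return ev
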