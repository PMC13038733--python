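"""Shared fixtures: small protocols and simulated recordings."""

import numpy as np
import pytest

from skytuner import (
    Direction,
    RotationSegment,
    SpikeTrain,
    StimulusKind,
    StimulusProtocol,
    make_protocol,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def polarizer_segment():
    """One cw polarizer block: 3 turns at 30°/s starting at t=10 s."""
    return RotationSegment(
        stimulus_kind=StimulusKind.POLARIZER_BLUE,
        direction=Direction.CW,
        angular_velocity=30.0,
        start_time=10.0,
        n_turns=3,
    )


@pytest.fixture
def standard_protocol():
    """The typical session: 3 cw + 3 ccw polarizer rotations at 30°/s with
    off gaps for background estimation."""
    return make_protocol(velocities=(30.0,), n_turns=3, off_gap=30.0)


def spikes_at_angles(segment: RotationSegment, turn: int, angles_deg):
    """Place spikes at given presented angles within one turn of a segment
    (inverse of the time→angle map); returns sorted absolute times."""
    t0 = segment.start_time + turn * segment.turn_duration
    rel = [
        (a % 360.0) / segment.angular_velocity
        if segment.direction is Direction.CW
        else ((360.0 - a % 360.0) % 360.0) / segment.angular_velocity
        for a in angles_deg
    ]
    return np.sort(t0 + np.asarray(rel))


@pytest.fixture
def spike_placer():
    return spikes_at_angles
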