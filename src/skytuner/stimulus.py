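"""Stimulus schedule representation and spike-time → stimulus-angle mapping.

The experiments this package targets rotate a visual stimulus — a linear
polarizer overhead, or an unpolarized light spot circling the head — around
the animal while spikes are recorded intracellularly.  Everything downstream
(tuning curves, preferred angles) needs to know which stimulus angle was on
display at each spike time.  This module holds the machine-readable schedule
(:class:`StimulusProtocol`) and the conversion from absolute recording time
to presented angle per single 360° rotation ("trial").

Conventions
-----------
* Angles are degrees in the half-open interval [0, 360); a polarizer's
  E-vector orientation is additionally periodic with 180°.
* Clockwise (cw) rotation increases the angle (0°→360°), counterclockwise
  (ccw) decreases it (360°→0°).
* All time windows are half-open ``[t_start, t_end)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "StimulusKind",
    "Direction",
    "RotationSegment",
    "StimulusProtocol",
    "SpikeTrain",
    "TrialWindow",
    "OutOfWindowError",
    "angle_at_time",
    "rotation_windows",
    "spike_angles",
]


class StimulusKind(str, enum.Enum):
    """The three rotating stimuli used to probe sky-compass sensitivity."""

    POLARIZER_BLUE = "polarizer_blue"
    SPOT_GREEN = "spot_green"
    SPOT_UV = "spot_uv"

    @property
    def periodicity(self) -> int:
        """Angular period in degrees: 180 for the polarizer (an E-vector
        orientation is an axis, not a direction), 360 for light spots."""
        return 180 if self is StimulusKind.POLARIZER_BLUE else 360

    @property
    def default_elevation(self) -> float:
        """Stimulus elevation in degrees: zenith for the polarizer, 45 for
        the circling light spots."""
        return 90.0 if self is StimulusKind.POLARIZER_BLUE else 45.0


class Direction(str, enum.Enum):
    CW = "cw"
    CCW = "ccw"

    @property
    def sign(self) -> int:
        """+1 for cw (angle increasing), −1 for ccw."""
        return 1 if self is Direction.CW else -1


class OutOfWindowError(ValueError):
    """Raised when a time is queried outside a segment's rotation window."""


@dataclass(frozen=True)
class RotationSegment:
    """One block of consecutive full 360° rotations of a single stimulus.

    Parameters
    ----------
    stimulus_kind:
        Which stimulus rotates.
    direction:
        Rotation direction (cw = increasing angle).
    angular_velocity:
        Rotation speed in degrees per second, > 0.  The experiments used
        30, 40 or 60 °/s but any positive value is accepted.
    start_time:
        Absolute recording time (s) at which the first rotation starts.
    start_angle:
        Presented angle at ``start_time``; defaults to 0° (E-vector parallel
        to the body axis, or light spot straight ahead).
    n_turns:
        Number of consecutive full 360° rotations in the block.
    elevation, visual_angle:
        Stimulus geometry metadata; not used in the analysis.
    """

    stimulus_kind: StimulusKind
    direction: Direction
    angular_velocity: float
    start_time: float
    start_angle: float = 0.0
    n_turns: int = 3
    elevation: float | None = None
    visual_angle: float | None = None

    def __post_init__(self) -> None:
        if self.angular_velocity <= 0:
            raise ValueError("angular_velocity must be > 0")
        if self.start_time < 0:
            raise ValueError("start_time must be >= 0")
        if not 0 <= self.start_angle < 360:
            raise ValueError("start_angle must be in [0, 360)")
        if self.n_turns < 0:
            raise ValueError("n_turns must be >= 0")
        if self.elevation is None:
            object.__setattr__(
                self, "elevation", self.stimulus_kind.default_elevation
            )

    @property
    def periodicity(self) -> int:
        return self.stimulus_kind.periodicity

    @property
    def turn_duration(self) -> float:
        """Seconds per full 360° rotation."""
        return 360.0 / self.angular_velocity

    @property
    def duration(self) -> float:
        return self.n_turns * self.turn_duration

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration


@dataclass(frozen=True)
class StimulusProtocol:
    """The full stimulus schedule of one recording session.

    ``off_intervals`` are periods with all stimuli switched off (used for
    background-activity estimation); ``stationary_intervals`` are lights-on
    but non-rotating periods (excluded from both tuning and background).
    """

    segments: tuple[RotationSegment, ...]
    off_intervals: tuple[tuple[float, float], ...] = ()
    stationary_intervals: tuple[
        tuple[float, float, StimulusKind, float], ...
    ] = ()
    exclude_first_rotation: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        object.__setattr__(
            self, "off_intervals", tuple(tuple(i) for i in self.off_intervals)
        )
        object.__setattr__(
            self,
            "stationary_intervals",
            tuple(tuple(i) for i in self.stationary_intervals),
        )
        spans = [(s.start_time, s.end_time) for s in self.segments]
        spans += [(a, b) for a, b in self.off_intervals]
        spans += [(a, b, *_) for (a, b, *_) in self.stationary_intervals]
        for a, b, *_ in spans:
            if b < a:
                raise ValueError(f"interval ({a}, {b}) has negative length")
        ordered = sorted((a, b) for a, b, *_ in spans)
        for (a1, b1), (a2, b2) in zip(ordered, ordered[1:]):
            if a2 < b1:
                raise ValueError(
                    f"protocol intervals overlap: [{a1},{b1}) and [{a2},{b2})"
                )

    @property
    def span(self) -> tuple[float, float]:
        """(earliest start, latest end) over every scheduled interval."""
        starts = [s.start_time for s in self.segments]
        ends = [s.end_time for s in self.segments]
        starts += [a for a, _ in self.off_intervals]
        ends += [b for _, b in self.off_intervals]
        starts += [a for a, b, *_ in self.stationary_intervals]
        ends += [b for a, b, *_ in self.stationary_intervals]
        if not starts:
            return (0.0, 0.0)
        return (min(starts), max(ends))


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike event times (seconds) from one recording."""

    times: np.ndarray
    recording_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float).ravel()
        if t.size and np.any(t < 0):
            raise ValueError("spike times must be non-negative")
        if t.size and np.any(np.diff(t) < 0):
            raise ValueError("spike times must be sorted non-decreasing")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class TrialWindow:
    """One retained single 360° rotation of a stimulus."""

    segment: RotationSegment
    turn_index: int
    t_start: float
    t_end: float

    @property
    def direction(self) -> Direction:
        return self.segment.direction

    @property
    def stimulus_kind(self) -> StimulusKind:
        return self.segment.stimulus_kind

    @property
    def angular_velocity(self) -> float:
        return self.segment.angular_velocity


def angle_at_time(segment: RotationSegment, t: float) -> float:
    """Presented stimulus angle (degrees in [0, 360)) at absolute time ``t``.

    cw motion advances the angle linearly from ``start_angle``; ccw motion
    retreats it.  ``t`` must lie inside the segment's half-open time window.
    """
    if not (segment.start_time <= t < segment.end_time):
        raise OutOfWindowError(
            f"t={t} outside segment window "
            f"[{segment.start_time}, {segment.end_time})"
        )
    dt = t - segment.start_time
    ang = segment.start_angle + segment.direction.sign * segment.angular_velocity * dt
    return float(np.mod(ang, 360.0))


def rotation_windows(protocol: StimulusProtocol) -> list[TrialWindow]:
    """Split every segment into its single full-turn trial windows.

    Each full 360° rotation becomes one :class:`TrialWindow`.  When
    ``protocol.exclude_first_rotation`` is true, the first presented turn of
    each *stimulus kind* is dropped — stimulus onset typically produces a
    phasic transient unrelated to angular tuning, so the first rotation of
    each stimulus is not evaluated.  Windows are returned in chronological
    order.
    """
    windows: list[TrialWindow] = []
    for seg in sorted(protocol.segments, key=lambda s: s.start_time):
        for k in range(seg.n_turns):
            t0 = seg.start_time + k * seg.turn_duration
            windows.append(TrialWindow(seg, k, t0, t0 + seg.turn_duration))
    if protocol.exclude_first_rotation:
        seen: set[StimulusKind] = set()
        kept: list[TrialWindow] = []
        for w in windows:  # already chronological
            if w.stimulus_kind not in seen:
                seen.add(w.stimulus_kind)
                continue
            kept.append(w)
        windows = kept
    return windows


def spike_angles(spikes: SpikeTrain, window: TrialWindow) -> np.ndarray:
    """Stimulus angles (degrees in [0, 360)) of every spike inside a trial.

    Spikes in ``[t_start, t_end)`` are converted via :func:`angle_at_time`;
    spike order is preserved.  An empty result is valid.
    """
    t = spikes.times
    sel = t[(t >= window.t_start) & (t < window.t_end)]
    seg = window.segment
    dt = sel - window.t_start
    # angle at the start of *this* turn equals the segment start angle
    # (each turn spans exactly 360°), so the per-turn formula reuses it
    ang = seg.start_angle + seg.direction.sign * seg.angular_velocity * dt
    return np.mod(ang, 360.0)
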