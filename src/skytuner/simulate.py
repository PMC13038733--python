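"""Synthetic electrophysiology: parametric neuron models driven by a
stimulus protocol.

Spike trains are drawn from an inhomogeneous Poisson process whose
intensity follows a cosine tuning curve locked to the rotating stimulus:

    λ(t) = clip( b + A·cos( k·(φ(t) − Φ_max − s·δ) ) )  during rotation,
    λ(t) = b                                             otherwise,

with background rate *b*, modulation amplitude *A*, harmonic *k* (1 for
azimuthal 360°-periodic tuning, 2 for axial 180°-periodic polarization
tuning), true preferred angle Φ_max, rotation-direction sign *s* (+1 cw,
−1 ccw) and anticipatory lead δ applied against the rotation direction.
Opponent neurons may be driven below background (floored at 0, giving the
characteristic inhibition trough at the anti-preferred angle); non-opponent
neurons only add the positive half-wave on top of background.  Optional
exponential onset transients model the phasic burst at lights-on.

Sampling uses Poisson thinning against the global rate ceiling, so the
generated trains are exact draws from λ(t) and reproducible from a single
integer seed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .stimulus import (
    Direction,
    RotationSegment,
    SpikeTrain,
    StimulusKind,
    StimulusProtocol,
)

__all__ = [
    "OffsetResponse",
    "NeuronModelParams",
    "rate_function",
    "simulate_spike_train",
    "scenario_library",
    "make_protocol",
]


class OffsetResponse(str, enum.Enum):
    NONE = "none"
    PHASIC = "phasic"
    INHIBITION = "inhibition"


@dataclass(frozen=True)
class NeuronModelParams:
    """Generative parameters of one model neuron.

    Parameters
    ----------
    background_rate:
        Spontaneous rate *b* in impulses·s⁻¹ (≥ 0).
    modulation_amplitude:
        Peak modulation *A* in impulses·s⁻¹ (≥ 0); A = 0 gives an untuned
        control neuron.
    harmonic:
        1 for azimuthal (360°-periodic) tuning to a light spot, 2 for axial
        (180°-periodic) tuning to the polarizer's E-vector.
    true_phi_max:
        Preferred angle in degrees, in [0, 360/harmonic).
    anticipatory_shift:
        Angular lead δ (degrees, ≥ 0) applied against the rotation
        direction; produces a cw/ccw Φ_max mismatch of 2δ.
    onset_amplitude, onset_tau:
        Exponential phasic transient added after each lights-on event.
    offset_response:
        Behaviour after lights-off: none, a phasic burst, or transient
        suppression of the background.
    opponent:
        Whether the modulation may drive the rate below background
        (floored at 0), producing inhibition at the anti-preferred angle.
    """

    background_rate: float = 10.0
    modulation_amplitude: float = 10.0
    harmonic: int = 2
    true_phi_max: float = 0.0
    anticipatory_shift: float = 0.0
    onset_amplitude: float = 0.0
    onset_tau: float = 0.5
    offset_response: OffsetResponse = OffsetResponse.NONE
    opponent: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        if self.background_rate < 0 or self.modulation_amplitude < 0:
            raise ValueError("rates must be non-negative")
        if self.harmonic not in (1, 2):
            raise ValueError("harmonic must be 1 (azimuthal) or 2 (axial)")
        if self.anticipatory_shift < 0:
            raise ValueError("anticipatory_shift must be >= 0")
        if self.onset_tau <= 0:
            raise ValueError("onset_tau must be > 0")

    @property
    def periodicity(self) -> int:
        return 360 // self.harmonic

    @property
    def rate_ceiling(self) -> float:
        return self.background_rate + self.modulation_amplitude + abs(
            self.onset_amplitude
        )


def _lights_on_times(protocol: StimulusProtocol) -> np.ndarray:
    """Start times of merged lights-on periods (rotations + stationary)."""
    spans = [(s.start_time, s.end_time) for s in protocol.segments]
    spans += [(a, b) for a, b, *_ in protocol.stationary_intervals]
    if not spans:
        return np.empty(0)
    spans.sort()
    merged = [list(spans[0])]
    for a, b in spans[1:]:
        if a <= merged[-1][1] + 1e-9:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return np.asarray([a for a, _ in merged])


def _lights_off_times(protocol: StimulusProtocol) -> np.ndarray:
    spans = [(s.start_time, s.end_time) for s in protocol.segments]
    spans += [(a, b) for a, b, *_ in protocol.stationary_intervals]
    if not spans:
        return np.empty(0)
    spans.sort()
    merged = [list(spans[0])]
    for a, b in spans[1:]:
        if a <= merged[-1][1] + 1e-9:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return np.asarray([b for _, b in merged])


def rate_function(
    params: NeuronModelParams,
    protocol: StimulusProtocol,
    t,
) -> np.ndarray:
    """Deterministic firing intensity λ(t) in impulses·s⁻¹ (vectorised).

    Off and stationary periods sit at the background rate *b* (plus any
    onset/offset transients); during rotation the cosine modulation is
    locked to the presented angle with the anticipatory lead applied
    against the rotation direction.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    lam = np.full_like(t, params.background_rate)
    b, A = params.background_rate, params.modulation_amplitude
    for seg in protocol.segments:
        sel = (t >= seg.start_time) & (t < seg.end_time)
        if not np.any(sel):
            continue
        dt = t[sel] - seg.start_time
        phi = np.mod(
            seg.start_angle + seg.direction.sign * seg.angular_velocity * dt,
            360.0,
        )
        shift = seg.direction.sign * params.anticipatory_shift
        mod = A * np.cos(
            np.deg2rad(params.harmonic * (phi - params.true_phi_max - shift))
        )
        if params.opponent:
            lam[sel] = np.maximum(0.0, b + mod)
        else:
            lam[sel] = b + np.maximum(0.0, mod)
    if params.onset_amplitude != 0.0:
        for t_on in _lights_on_times(protocol):
            sel = t >= t_on
            lam[sel] += params.onset_amplitude * np.exp(
                -(t[sel] - t_on) / params.onset_tau
            )
    if params.offset_response is not OffsetResponse.NONE:
        amp = params.onset_amplitude if params.onset_amplitude else b
        sign = 1.0 if params.offset_response is OffsetResponse.PHASIC else -1.0
        for t_off in _lights_off_times(protocol):
            sel = t >= t_off
            lam[sel] += sign * amp * np.exp(
                -(t[sel] - t_off) / params.onset_tau
            )
    return np.maximum(lam, 0.0)


def simulate_spike_train(
    params: NeuronModelParams,
    protocol: StimulusProtocol,
    seed: int | np.random.Generator = 0,
) -> SpikeTrain:
    """Draw a spike train from the inhomogeneous Poisson model by thinning.

    Candidate events are sampled homogeneously at the rate ceiling
    λ_max = b + A + |onset amplitude| over the protocol span and accepted
    with probability λ(t)/λ_max.  Output is sorted and exactly reproducible
    for a fixed integer seed.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    t0, t1 = protocol.span
    span = t1 - t0
    lam_max = params.rate_ceiling
    if span <= 0 or lam_max <= 0:
        return SpikeTrain(np.empty(0), recording_id=params.name)
    n_cand = rng.poisson(lam_max * span)
    cand = np.sort(rng.uniform(t0, t1, size=n_cand))
    if n_cand == 0:
        return SpikeTrain(np.empty(0), recording_id=params.name)
    accept = rng.uniform(0.0, 1.0, size=n_cand) * lam_max < rate_function(
        params, protocol, cand
    )
    return SpikeTrain(cand[accept], recording_id=params.name)


def scenario_library() -> dict[str, NeuronModelParams]:
    """Named generative presets spanning the response phenotypes observed
    in sky-compass neurons.

    The preferred angles and background rates are taken from published
    per-neuron values; modulation depths are chosen to reproduce the
    qualitative phenotype (opponency, complete inhibition, untuned) and,
    for ``PC4``, the observed mean-vector length (A = 2b gives r ≈ 0.66
    for the floored opponent cosine).
    """
    return {
        # axial polarization-opponent commissural neuron: Φ_max 51.8°,
        # background 9.0 imp/s, rate driven to 0 at the anti-preferred angle
        "PC4": NeuronModelParams(
            background_rate=9.0,
            modulation_amplitude=18.0,
            harmonic=2,
            true_phi_max=51.8,
            opponent=True,
            name="PC4",
        ),
        # azimuthal UV-spot tuning with complete inhibition opposite the
        # preferred azimuth: Φ_max 94.3°, high background 30.7 imp/s
        "PC5_UV": NeuronModelParams(
            background_rate=30.7,
            modulation_amplitude=40.0,
            harmonic=1,
            true_phi_max=94.3,
            opponent=True,
            name="PC5_UV",
        ),
        # same cell's green-spot response: similar azimuth (84.4°) but no
        # inhibition below background at the opposite azimuth
        "PC5_GREEN": NeuronModelParams(
            background_rate=30.7,
            modulation_amplitude=20.0,
            harmonic=1,
            true_phi_max=84.4,
            opponent=False,
            name="PC5_GREEN",
        ),
        # lobula projection neuron with anticipatory lead: pooled axial
        # Φ_max 128.2°, cw/ccw mismatch ≈ 46.6° ⇒ δ = 23.3°; phasic
        # lights-on burst, background 13.7 imp/s
        "LOXPN1": NeuronModelParams(
            background_rate=13.7,
            modulation_amplitude=14.0,
            harmonic=2,
            true_phi_max=128.2,
            anticipatory_shift=23.3,
            onset_amplitude=20.0,
            onset_tau=0.5,
            opponent=True,
            name="LOXPN1",
        ),
        # untuned control: protocerebral-bridge neuron unresponsive to the
        # polarization angle, background 17.3 imp/s
        "TB1c": NeuronModelParams(
            background_rate=17.3,
            modulation_amplitude=0.0,
            harmonic=2,
            true_phi_max=0.0,
            opponent=False,
            name="TB1c",
        ),
        # low-background tangential neuron, weak axial excitation
        "TB4_LOW": NeuronModelParams(
            background_rate=4.9,
            modulation_amplitude=3.0,
            harmonic=2,
            true_phi_max=60.0,
            opponent=False,
            name="TB4_LOW",
        ),
    }


def make_protocol(
    stimulus_kinds=(StimulusKind.POLARIZER_BLUE,),
    velocities=(30.0,),
    n_turns: int = 3,
    directions=(Direction.CW, Direction.CCW),
    off_gap: float = 30.0,
    exclude_first_rotation: bool = True,
) -> StimulusProtocol:
    """Build a well-formed protocol of alternating cw/ccw rotation blocks.

    For each stimulus kind (paired with a velocity from ``velocities``,
    recycled if shorter) one block of ``n_turns`` full rotations per
    direction is scheduled, separated by stimulus-off gaps of ``off_gap``
    seconds, with leading and trailing off intervals for background
    estimation.
    """
    kinds = [
        StimulusKind(k) if isinstance(k, str) else k for k in stimulus_kinds
    ]
    dirs = [Direction(d) if isinstance(d, str) else d for d in directions]
    if n_turns < 1:
        raise ValueError("n_turns must be >= 1")
    segments: list[RotationSegment] = []
    off: list[tuple[float, float]] = []
    t = 0.0
    off.append((t, t + off_gap))
    t += off_gap
    for i, kind in enumerate(kinds):
        v = float(velocities[i % len(velocities)])
        if v <= 0:
            raise ValueError(f"angular velocity {v} must be > 0")
        for d in dirs:
            seg = RotationSegment(
                stimulus_kind=kind,
                direction=d,
                angular_velocity=v,
                start_time=t,
                n_turns=n_turns,
            )
            segments.append(seg)
            t = seg.end_time
        off.append((t, t + off_gap))
        t += off_gap
    return StimulusProtocol(
        segments=tuple(segments),
        off_intervals=tuple(off),
        exclude_first_rotation=exclude_first_rotation,
    )
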