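"""End-to-end per-neuron tuning analysis.

Chains the stimulus mapping and circular statistics into the full analysis
applied to each recording: estimate background activity from stimulus-off
periods, convert spikes in each retained rotation to stimulus angles, bin
them into per-trial firing-rate histograms, average across cw/ccw trial
pairs, and summarise tuning as Φ_max, mean-vector length r, circular SD,
95% confidence arc, and the linear-circular R² with its p-value.  Also
provides the opponency classifier (excitation at Φ_max with inhibition
below background at Φ_min), the cw/ccw Φ_max mismatch, and a moving-average
firing-rate trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from . import circstats
from .circstats import (
    NoPreferredAngleError,
    UndefinedStatisticError,
    ci95_mean_direction,
    circ_sd_from_r,
    circular_distance,
    linear_circular_corr,
    phi_max as _phi_max,
    resultant,
)
from .stimulus import (
    Direction,
    SpikeTrain,
    StimulusKind,
    StimulusProtocol,
    TrialWindow,
    rotation_windows,
    spike_angles,
)

__all__ = [
    "BackgroundActivity",
    "BinnedTuning",
    "TuningResult",
    "InsufficientDataError",
    "background_stats",
    "bin_spike_angles",
    "compute_tuning",
    "opponency_classification",
    "direction_mismatch",
    "moving_average_rate",
]

Group = Literal["cw", "ccw", "both"]


class InsufficientDataError(ValueError):
    """Not enough baseline time or retained trials for the analysis."""


@dataclass(frozen=True)
class BackgroundActivity:
    """Spontaneous firing statistics from stimulus-off periods.

    ``mean_rate`` and ``sd`` are over consecutive non-overlapping 1-s bins
    placed inside the off intervals (partial trailing bins discarded)."""

    mean_rate: float
    sd: float
    n_bins: int
    source_intervals: tuple[tuple[float, float], ...]


@dataclass(frozen=True)
class BinnedTuning:
    """Per-trial angular spike-count histograms and across-pair averages.

    ``per_trial_rates`` converts counts to impulses·s⁻¹ by dividing by the
    dwell time of one bin, ``bin_width / angular_velocity`` of that trial,
    so trials at different rotation velocities are comparable.  Mean and SD
    per bin are taken across cw/ccw trial pairs (pairs formed in
    presentation order; an unpaired leftover trial counts as a singleton
    pair), matching the error bars of the circular histograms.
    """

    bin_width: float
    bin_edges: np.ndarray
    per_trial_counts: np.ndarray  # trials × bins
    per_trial_rates: np.ndarray  # trials × bins, imp/s
    mean_rate_per_bin: np.ndarray
    sd_per_bin: np.ndarray
    n_rotations: int
    group: Group
    trial_directions: tuple[str, ...] = ()

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


@dataclass(frozen=True)
class TuningResult:
    """Tuning summary for one neuron × stimulus × rotation group.

    ``phi_max`` is ``None`` when no preferred angle exists (vanishing
    resultant); ``R2`` is withheld (``None``) whenever the linear-circular
    correlation is not significant at the chosen alpha, so serialized
    results mirror the convention of reporting R² only for significant
    tunings.
    """

    stimulus_kind: StimulusKind
    group: Group
    periodicity: int
    phi_max: float | None
    r: float
    circ_sd: float | None
    ci95_halfarc: float | None
    R2: float | None
    p: float
    significant: bool
    n_rotations: int
    n_samples: int
    n_spikes: int
    background: BackgroundActivity | None = None


# ---------------------------------------------------------------------------
# background activity
# ---------------------------------------------------------------------------

def background_stats(
    spikes: SpikeTrain,
    protocol: StimulusProtocol,
    bin_seconds: float = 1.0,
) -> BackgroundActivity:
    """Mean ± SD background rate from 1-s bins inside stimulus-off periods.

    Only complete bins fully inside an off interval are used; a partial
    trailing bin is discarded.  Raises :class:`InsufficientDataError` when
    fewer than two complete bins are available.
    """
    counts: list[int] = []
    used: list[tuple[float, float]] = []
    t = spikes.times
    for a, b in protocol.off_intervals:
        n_full = int(math.floor((b - a) / bin_seconds + 1e-9))
        if n_full < 1:
            continue
        edges = a + bin_seconds * np.arange(n_full + 1)
        c, _ = np.histogram(t, bins=edges)
        counts.extend(int(x) for x in c)
        used.append((a, float(edges[-1])))
    if len(counts) < 2:
        raise InsufficientDataError(
            f"only {len(counts)} complete {bin_seconds:g}-s background bins; "
            "need at least 2"
        )
    arr = np.asarray(counts, dtype=float) / bin_seconds
    return BackgroundActivity(
        mean_rate=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        n_bins=len(counts),
        source_intervals=tuple(used),
    )


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def _pair_indices(directions: Sequence[str]) -> list[tuple[int, ...]]:
    """Pair cw with ccw trials in presentation order; leftovers become
    singleton pairs."""
    cw = [i for i, d in enumerate(directions) if d == "cw"]
    ccw = [i for i, d in enumerate(directions) if d == "ccw"]
    pairs: list[tuple[int, ...]] = [
        (i, j) for i, j in zip(cw, ccw)
    ]
    extra = cw[len(ccw):] + ccw[len(cw):]
    pairs.extend((i,) for i in extra)
    return pairs


def bin_spike_angles(
    trials: Sequence[tuple[TrialWindow, np.ndarray]],
    bin_width: float = 15.0,
    group: Group = "both",
) -> BinnedTuning:
    """Histogram per-trial spike angles into fixed angular bins.

    ``trials`` pairs each retained :class:`TrialWindow` with the spike
    angles recorded during it.  Bins are half-open ``[a, a + width)``
    anchored at 0°; ``bin_width`` must divide 360.  Rates use the dwell
    time ``bin_width / angular_velocity`` of each trial's own velocity.
    """
    if bin_width <= 0 or abs(360.0 / bin_width - round(360.0 / bin_width)) > 1e-9:
        raise ValueError(f"bin_width {bin_width} does not divide 360")
    if len(trials) == 0:
        raise InsufficientDataError("no trials to bin")
    n_bins = int(round(360.0 / bin_width))
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    counts = np.zeros((len(trials), n_bins))
    rates = np.zeros_like(counts)
    directions: list[str] = []
    for i, (window, angles) in enumerate(trials):
        a = np.mod(np.asarray(angles, dtype=float), 360.0)
        idx = np.minimum((a / bin_width).astype(int), n_bins - 1)
        np.add.at(counts[i], idx, 1.0)
        dwell = bin_width / window.angular_velocity
        rates[i] = counts[i] / dwell
        directions.append(window.direction.value)
    pair_means = np.stack(
        [rates[list(p)].mean(axis=0) for p in _pair_indices(directions)]
    )
    mean = pair_means.mean(axis=0)
    sd = (
        pair_means.std(axis=0, ddof=1)
        if pair_means.shape[0] > 1
        else np.zeros(n_bins)
    )
    return BinnedTuning(
        bin_width=float(bin_width),
        bin_edges=edges,
        per_trial_counts=counts,
        per_trial_rates=rates,
        mean_rate_per_bin=mean,
        sd_per_bin=sd,
        n_rotations=len(trials),
        group=group,
        trial_directions=tuple(directions),
    )


# ---------------------------------------------------------------------------
# tuning summary
# ---------------------------------------------------------------------------

def _collect_trials(
    spikes: SpikeTrain,
    protocol: StimulusProtocol,
    stimulus_kind: StimulusKind,
    group: Group,
) -> list[tuple[TrialWindow, np.ndarray]]:
    out = []
    for w in rotation_windows(protocol):
        if w.stimulus_kind is not stimulus_kind:
            continue
        if group != "both" and w.direction.value != group:
            continue
        out.append((w, spike_angles(spikes, w)))
    return out


def compute_tuning(
    spikes: SpikeTrain,
    protocol: StimulusProtocol,
    stimulus_kind: StimulusKind | str = StimulusKind.POLARIZER_BLUE,
    group: Group = "both",
    bin_width: float = 15.0,
    alpha: float = 0.05,
    phi_from: Literal["spikes", "bins"] = "spikes",
    sd_convention: str = "angular_deviation",
    background: BackgroundActivity | None = None,
) -> TuningResult:
    """Full tuning analysis for one neuron × stimulus × rotation group.

    Φ_max and r are computed from the pooled individual spike angles of all
    retained trials (each spike contributing one unit vector); with
    ``phi_from="bins"`` the per-bin mean rates are used as weights at the
    bin centers instead.  Polarizer data are treated axially (angles
    doubled, result halved).  The significance gate is the linear-circular
    correlation between per-bin mean rate and bin-center angle: n = number
    of bins samples, p from χ²₂ at n·R²; R² is withheld when p ≥ alpha.
    """
    if isinstance(stimulus_kind, str):
        stimulus_kind = StimulusKind(stimulus_kind)
    trials = _collect_trials(spikes, protocol, stimulus_kind, group)
    if not trials:
        raise InsufficientDataError(
            f"no retained {group} trials of {stimulus_kind.value}"
        )
    periodicity = stimulus_kind.periodicity
    binned = bin_spike_angles(trials, bin_width, group)
    pooled = (
        np.concatenate([a for _, a in trials])
        if any(a.size for _, a in trials)
        else np.empty(0)
    )
    n_spikes = int(pooled.size)

    # preferred angle and vector strength
    phi: float | None
    if phi_from == "bins":
        angles_in, weights = binned.bin_centers, binned.mean_rate_per_bin
    else:
        angles_in, weights = pooled, None
    try:
        if angles_in.size == 0:
            raise NoPreferredAngleError("no spikes in retained trials")
        doubled = (
            circstats.axial_double(angles_in)
            if periodicity == 180
            else angles_in
        )
        _, r = resultant(doubled, weights)
        phi = _phi_max(angles_in, periodicity, weights)
    except (NoPreferredAngleError, UndefinedStatisticError):
        phi, r = None, 0.0

    csd = circ_sd_from_r(r, sd_convention) if phi is not None else None
    n_for_ci = n_spikes if phi_from == "spikes" else binned.n_bins
    ci = (
        ci95_mean_direction(n_for_ci, r, periodicity)
        if phi is not None and n_for_ci >= 2
        else None
    )

    # significance gate: rate-vs-angle linear-circular correlation over bins
    try:
        r2, p = linear_circular_corr(
            binned.mean_rate_per_bin, binned.bin_centers, periodicity
        )
    except UndefinedStatisticError:
        r2, p = 0.0, 1.0
    significant = p < alpha
    return TuningResult(
        stimulus_kind=stimulus_kind,
        group=group,
        periodicity=periodicity,
        phi_max=phi,
        r=r,
        circ_sd=csd,
        ci95_halfarc=ci,
        R2=r2 if significant else None,
        p=p,
        significant=significant,
        n_rotations=binned.n_rotations,
        n_samples=binned.n_bins,
        n_spikes=n_spikes,
        background=background,
    )


# ---------------------------------------------------------------------------
# qualitative classifiers
# ---------------------------------------------------------------------------

def opponency_classification(
    binned: BinnedTuning,
    background: BackgroundActivity,
    phi_max_deg: float | None,
    periodicity: int = 360,
) -> str:
    """Classify a tuning curve as ``"opponent"``, ``"excitation_only"`` or
    ``"none"``.

    Opponent: the bin containing the anti-preferred angle Φ_min
    (Φ_max + periodicity/2) falls below background mean − SD *and* the bin
    at Φ_max rises above background mean + SD.  Excitation-only: only the
    excitation criterion holds.
    """
    if phi_max_deg is None:
        return "none"
    width = binned.bin_width
    n_bins = binned.n_bins

    def _bin_rate(angle: float) -> float:
        idx = int(np.mod(angle, 360.0) / width) % n_bins
        return float(binned.mean_rate_per_bin[idx])

    phi_min = (phi_max_deg + periodicity / 2.0) % 360.0
    excited = _bin_rate(phi_max_deg) > background.mean_rate + background.sd
    inhibited = _bin_rate(phi_min) < background.mean_rate - background.sd
    if periodicity == 180:
        # an axial tuning repeats at +180°; both representatives must agree
        excited = excited and (
            _bin_rate(phi_max_deg + 180.0)
            > background.mean_rate + background.sd
        )
        inhibited = inhibited and (
            _bin_rate(phi_min + 180.0) < background.mean_rate - background.sd
        )
    if excited and inhibited:
        return "opponent"
    if excited:
        return "excitation_only"
    return "none"


def direction_mismatch(
    result_cw: TuningResult, result_ccw: TuningResult
) -> float:
    """Smallest angular distance between cw and ccw Φ_max, in
    [0, periodicity/2].  An anticipatory shift δ against rotation direction
    shows up here as a mismatch of 2δ."""
    if result_cw.periodicity != result_ccw.periodicity:
        raise ValueError("results have different periodicities")
    if result_cw.phi_max is None or result_ccw.phi_max is None:
        raise UndefinedStatisticError("Φ_max undefined for one group")
    return circular_distance(
        result_cw.phi_max, result_ccw.phi_max, result_cw.periodicity
    )


# ---------------------------------------------------------------------------
# rate trace
# ---------------------------------------------------------------------------

def moving_average_rate(
    spikes: SpikeTrain,
    window: float = 1.0,
    grid_step: float = 0.01,
    t_start: float | None = None,
    t_end: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Centered moving-average firing rate on a uniform time grid.

    At each grid point the spikes within ±window/2 are counted and divided
    by the window duration actually covered (edges use truncated windows),
    in impulses·s⁻¹.  Returns ``(grid_times, rates)``.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    t = spikes.times
    if t_start is None:
        t_start = float(t[0]) if t.size else 0.0
    if t_end is None:
        t_end = float(t[-1]) if t.size else t_start + window
    grid = np.arange(t_start, t_end + grid_step / 2, grid_step)
    if t.size == 0:
        return grid, np.zeros_like(grid)
    half = window / 2.0
    lo = np.maximum(grid - half, t_start)
    hi = np.minimum(grid + half, t_end)
    counts = np.searchsorted(t, hi, side="left") - np.searchsorted(
        t, lo, side="left"
    )
    covered = np.maximum(hi - lo, grid_step)
    return grid, counts / covered
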