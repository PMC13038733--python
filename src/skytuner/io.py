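"""File formats, analysis configuration and report generation.

Spike trains travel as CSV with a mandatory ``time_s`` column; stimulus
protocols as YAML listing rotation segments and off/stationary intervals.
``run_analysis`` ties everything together: it reads both files, runs the
tuning pipeline per stimulus kind and rotation group, and writes JSON
results, binned-curve CSVs, a summary table, plot-ready polar-histogram
data, and a machine-readable run manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .pipeline import (
    BackgroundActivity,
    BinnedTuning,
    InsufficientDataError,
    TuningResult,
    background_stats,
    bin_spike_angles,
    compute_tuning,
    direction_mismatch,
    opponency_classification,
    _collect_trials,
)
from .circstats import UndefinedStatisticError
from .stimulus import (
    Direction,
    RotationSegment,
    SpikeTrain,
    StimulusKind,
    StimulusProtocol,
    rotation_windows,
)

__all__ = [
    "AnalysisConfig",
    "SpikeParseError",
    "read_spike_csv",
    "write_spike_csv",
    "read_protocol",
    "write_protocol",
    "run_analysis",
    "render_polarplot_data",
]

log = logging.getLogger("skytuner")


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis settings with the defaults used throughout.

    ``bin_width`` must divide 360 (10, 15 or 20° are typical);
    ``phi_from`` selects whether Φ_max/r come from pooled spike vectors
    (default) or from the binned mean rates; ``sd_convention`` picks the
    circular-spread formula.
    """

    bin_width: float = 15.0
    alpha: float = 0.05
    exclude_first_rotation: bool = True
    phi_from: str = "spikes"
    sd_convention: str = "angular_deviation"
    output_dir: str = "."

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if abs(360.0 / self.bin_width - round(360.0 / self.bin_width)) > 1e-9:
            raise ValueError(f"bin_width {self.bin_width} must divide 360")
        if self.phi_from not in ("spikes", "bins"):
            raise ValueError("phi_from must be 'spikes' or 'bins'")


class SpikeParseError(ValueError):
    """A spike CSV failed validation; the message names the offending line."""


def read_spike_csv(path) -> SpikeTrain:
    """Read a spike train from CSV (header with a ``time_s`` column).

    Non-monotone times are sorted with a warning; negative or non-numeric
    entries raise :class:`SpikeParseError` naming the data line.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise SpikeParseError(f"{path}: missing required column 'time_s'")
    raw = pd.to_numeric(df["time_s"], errors="coerce")
    bad = np.nonzero(raw.isna().to_numpy())[0]
    if bad.size:
        raise SpikeParseError(
            f"{path}: non-numeric time_s at data line {bad[0] + 2}"
        )
    t = raw.to_numpy(dtype=float)
    neg = np.nonzero(t < 0)[0]
    if neg.size:
        raise SpikeParseError(
            f"{path}: negative time_s at data line {neg[0] + 2}"
        )
    if t.size and np.any(np.diff(t) < 0):
        warnings.warn(f"{path}: time_s not sorted; sorting", stacklevel=2)
        t = np.sort(t)
    rec = ""
    if "recording_id" in df.columns and len(df):
        rec = str(df["recording_id"].iloc[0])
    return SpikeTrain(times=t, recording_id=rec)


def write_spike_csv(spikes: SpikeTrain, path) -> None:
    df = pd.DataFrame({"time_s": spikes.times})
    if spikes.recording_id:
        df["recording_id"] = spikes.recording_id
    df.to_csv(path, index=False)


def read_protocol(path) -> StimulusProtocol:
    """Read a stimulus protocol from its YAML description."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    segments = [
        RotationSegment(
            stimulus_kind=StimulusKind(s["stimulus_kind"]),
            direction=Direction(s["direction"]),
            angular_velocity=float(s["angular_velocity"]),
            start_time=float(s["start_time"]),
            start_angle=float(s.get("start_angle", 0.0)),
            n_turns=int(s.get("n_turns", 3)),
            elevation=s.get("elevation"),
            visual_angle=s.get("visual_angle"),
        )
        for s in doc.get("segments", [])
    ]
    stationary = tuple(
        (float(i[0]), float(i[1]), StimulusKind(i[2]), float(i[3]))
        for i in doc.get("stationary_intervals", [])
    )
    return StimulusProtocol(
        segments=tuple(segments),
        off_intervals=tuple(
            (float(a), float(b)) for a, b in doc.get("off_intervals", [])
        ),
        stationary_intervals=stationary,
        exclude_first_rotation=bool(doc.get("exclude_first_rotation", True)),
    )


def write_protocol(protocol: StimulusProtocol, path) -> None:
    doc = {
        "segments": [
            {
                "stimulus_kind": s.stimulus_kind.value,
                "direction": s.direction.value,
                "angular_velocity": s.angular_velocity,
                "start_time": s.start_time,
                "start_angle": s.start_angle,
                "n_turns": s.n_turns,
                "elevation": s.elevation,
                "visual_angle": s.visual_angle,
            }
            for s in protocol.segments
        ],
        "off_intervals": [list(i) for i in protocol.off_intervals],
        "stationary_intervals": [
            [a, b, k.value, ang]
            for a, b, k, ang in protocol.stationary_intervals
        ],
        "exclude_first_rotation": protocol.exclude_first_rotation,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _result_to_dict(res: TuningResult) -> dict:
    d = {
        "stimulus_kind": res.stimulus_kind.value,
        "group": res.group,
        "periodicity_deg": res.periodicity,
        "phi_max_deg": res.phi_max,
        "r": res.r,
        "circ_sd_deg": res.circ_sd,
        "ci95_halfarc_deg": res.ci95_halfarc,
        "p": res.p,
        "significant": res.significant,
        "n_rotations": res.n_rotations,
        "n_samples": res.n_samples,
        "n_spikes": res.n_spikes,
    }
    if res.significant:
        d["R2"] = res.R2
    if res.background is not None:
        d["background"] = {
            "mean_rate": res.background.mean_rate,
            "sd": res.background.sd,
            "n_bins": res.background.n_bins,
        }
    return d


def render_polarplot_data(
    binned: BinnedTuning,
    result: TuningResult | None = None,
    background: BackgroundActivity | None = None,
) -> pd.DataFrame:
    """Plot-ready table for a circular tuning histogram.

    One row per angular bin (center, mean rate, SD, constant background
    mean) plus one metadata row carrying Φ_max, r, and the CI arc bounds —
    everything needed to redraw the polar diagrams; fields are empty when
    Φ_max is undefined.
    """
    bg = background if background is not None else (
        result.background if result is not None else None
    )
    rows = pd.DataFrame(
        {
            "row_kind": "bin",
            "bin_center": binned.bin_centers,
            "mean_rate": binned.mean_rate_per_bin,
            "sd": binned.sd_per_bin,
            "background_mean": bg.mean_rate if bg is not None else np.nan,
            "phi_max": np.nan,
            "r": np.nan,
            "ci_lo": np.nan,
            "ci_hi": np.nan,
        }
    )
    meta = {
        "row_kind": "meta",
        "bin_center": np.nan,
        "mean_rate": np.nan,
        "sd": np.nan,
        "background_mean": bg.mean_rate if bg is not None else np.nan,
        "phi_max": np.nan,
        "r": np.nan,
        "ci_lo": np.nan,
        "ci_hi": np.nan,
    }
    if result is not None and result.phi_max is not None:
        meta["phi_max"] = result.phi_max
        meta["r"] = result.r
        if result.ci95_halfarc is not None:
            per = result.periodicity
            meta["ci_lo"] = (result.phi_max - result.ci95_halfarc) % per
            meta["ci_hi"] = (result.phi_max + result.ci95_halfarc) % per
    return pd.concat([rows, pd.DataFrame([meta])], ignore_index=True)


def run_analysis(
    config: AnalysisConfig,
    spikes_path,
    protocol_path,
    seed: int | None = None,
) -> dict:
    """Analyze one recording end to end and write the result bundle.

    Writes, under ``config.output_dir``: per-group ``TuningResult`` JSON,
    binned tuning-curve CSVs, plot-ready polar CSVs, a summary table with
    one row per stimulus × group, and a run manifest recording inputs,
    configuration and package version.  Returns the results as a dict
    keyed ``"<stimulus>_<group>"``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    spikes = read_spike_csv(spikes_path)
    protocol = read_protocol(protocol_path)
    if protocol.exclude_first_rotation != config.exclude_first_rotation:
        protocol = dataclasses.replace(
            protocol, exclude_first_rotation=config.exclude_first_rotation
        )
    try:
        background = background_stats(spikes, protocol)
    except InsufficientDataError as exc:
        log.warning("no background estimate: %s", exc)
        background = None

    kinds_present = {w.stimulus_kind for w in rotation_windows(protocol)}
    if not kinds_present:
        raise InsufficientDataError("protocol retains no rotation trials")
    results: dict[str, TuningResult] = {}
    summary_rows = []
    for kind in sorted(kinds_present, key=lambda k: k.value):
        for group in ("cw", "ccw", "both"):
            try:
                res = compute_tuning(
                    spikes,
                    protocol,
                    kind,
                    group,
                    bin_width=config.bin_width,
                    alpha=config.alpha,
                    phi_from=config.phi_from,
                    sd_convention=config.sd_convention,
                    background=background,
                )
            except InsufficientDataError:
                continue
            key = f"{kind.value}_{group}"
            results[key] = res
            with open(outdir / f"result_{key}.json", "w") as fh:
                json.dump(_result_to_dict(res), fh, indent=2)
            trials = _collect_trials(spikes, protocol, kind, group)
            binned = bin_spike_angles(trials, config.bin_width, group)
            pd.DataFrame(
                {
                    "bin_center": binned.bin_centers,
                    "mean_rate": binned.mean_rate_per_bin,
                    "sd": binned.sd_per_bin,
                    "n": binned.n_rotations,
                }
            ).to_csv(outdir / f"tuning_curve_{key}.csv", index=False)
            render_polarplot_data(binned, res, background).to_csv(
                outdir / f"polar_{key}.csv", index=False
            )
            opp = (
                opponency_classification(
                    binned, background, res.phi_max, res.periodicity
                )
                if background is not None
                else ""
            )
            summary_rows.append(
                {
                    "recording_id": spikes.recording_id,
                    "stimulus": kind.value,
                    "group": group,
                    "n": res.n_rotations,
                    "phi_max_deg": (
                        round(res.phi_max, 1)
                        if (res.significant and res.phi_max is not None)
                        else ""
                    ),
                    "r": round(res.r, 2) if res.significant else "",
                    "R2": (
                        round(res.R2, 2) if res.significant else "n.s."
                    ),
                    "p": res.p,
                    "opponency": opp,
                }
            )
    pd.DataFrame(summary_rows).to_csv(outdir / "summary.csv", index=False)

    cw_key = {k: results[k] for k in results if k.endswith("_cw")}
    mismatches = {}
    for k, res_cw in cw_key.items():
        k_ccw = k[: -len("_cw")] + "_ccw"
        if k_ccw in results:
            try:
                mismatches[k[: -len("_cw")]] = direction_mismatch(
                    res_cw, results[k_ccw]
                )
            except (UndefinedStatisticError, ValueError):
                pass
    manifest = {
        "skytuner_version": __version__,
        "spikes_path": str(spikes_path),
        "protocol_path": str(protocol_path),
        "config": dataclasses.asdict(config),
        "seed": seed,
        "n_spikes_total": len(spikes),
        "background": (
            {"mean_rate": background.mean_rate, "sd": background.sd,
             "n_bins": background.n_bins}
            if background is not None
            else None
        ),
        "direction_mismatch_deg": mismatches,
        "results": sorted(results),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    log.info("wrote %d result groups to %s", len(results), outdir)
    return results
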