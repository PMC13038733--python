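# Methods

## Stimulus model

A recording session is described by a `StimulusProtocol`: an ordered set of
`RotationSegment`s (stimulus kind, direction, angular velocity, start time,
start angle, number of full turns), stimulus-off intervals, and optional
stationary lights-on intervals. Clockwise rotation increases the presented
angle from the start angle (default 0°: E-vector parallel to the body axis,
or light spot straight ahead); counterclockwise decreases it. All windows
are half-open `[t_start, t_end)` and angles live in `[0°, 360°)`, so a
spike exactly at a window end or a bin edge belongs to the next interval,
never to two.

Each full 360° turn is one trial. When first-rotation exclusion is on (the
default), the first presented turn of each *stimulus kind* is dropped once
per session, because stimulus onset typically evokes a phasic transient
unrelated to angular tuning. The polarizer is axial (periodicity 180°);
light spots are azimuthal (360°). Stationary lights-on periods enter
neither the tuning analysis nor the background estimate; background uses
stimulus-off intervals only.

## Analysis chain

1. **Background**: spike counts in consecutive 1-s bins fully inside off
   intervals; mean and sample SD over bins; partial trailing bins are
   discarded; at least two complete bins are required.
2. **Spike angles**: every spike inside a retained trial window is mapped
   to its presented angle; trials keep their own angular velocity.
3. **Binning**: per-trial histograms over `[0°, 360°)` with bin width 10,
   15 (default) or 20° anchored at 0°; rates = counts ÷ dwell time
   (bin width ÷ that trial's velocity). cw and ccw trials are paired in
   presentation order (an unpaired leftover is a singleton pair); the
   reported per-bin mean and SD are across pairs.
4. **Φ_max and r**: by default from the pooled individual spike angles,
   each spike one unit vector (`phi_from="spikes"`); alternatively from
   the binned mean rates used as weights at bin centers
   (`phi_from="bins"`). For axial data the angles are doubled, the
   resultant computed, and the direction halved at the very end; all test
   statistics operate on the doubled scale.
5. **Spread**: circular SD defaults to the mean angular deviation
   (180/π)·√(2(1−r)), bounded by ≈81.03°; the unbounded convention
   (180/π)·√(−2 ln r) is available as an option.
6. **95% confidence arc**: the two-regime large-sample arc for a mean
   direction with χ²₀.₀₅,₁ ≈ 3.841 and R = n·r — for r ≤ 0.9,
   d = arccos(√(2n(2R² − nχ²)/(4n − χ²))/R), else
   d = arccos(√(n² − (n² − R²)e^{χ²/n})/R) — halved for axial data and
   undefined (reported as such) when the sample is too dispersed. The arc
   was validated against a bootstrap percentile arc (agreement within 2°
   at n = 100, r ≈ 0.8). A bootstrap would be the exact-sampling
   alternative; the analytic arc is the default because it is
   deterministic and standard.
7. **Significance gate**: linear-circular correlation of the per-bin mean
   rates against bin-center angles (doubled for axial data); the sample
   size of the test is the number of bins. R² is clipped to [0, 1] for
   reporting; the p-value (χ², 2 df, at n·R²) uses the unclipped
   statistic. Results with p ≥ 0.05 are reported "n.s." and their R² is
   withheld everywhere, including serialized output. No multiple-testing
   correction is applied. A vanishing resultant yields a typed
   "no preferred angle" outcome, reported downstream as non-significant.
8. **Opponency**: with Φ_min = Φ_max + periodicity/2, a curve is
   *opponent* if the bin at Φ_min falls below background mean − SD while
   the bin at Φ_max exceeds background mean + SD (for axial data both
   180°-separated representatives must agree), *excitation-only* if only
   the latter holds.
9. **Direction mismatch**: smallest angular distance between cw and ccw
   Φ_max under the shared periodicity; an anticipatory lead δ appears
   here as 2δ.

An auxiliary Rayleigh uniformity test (z = n·r², series tail
approximation, n ≥ 5) is provided for exploratory use; the significance
gate of the pipeline is the linear-circular correlation, not the Rayleigh
test.

## Generative model

The simulator draws spikes from an inhomogeneous Poisson process. During
rotation the intensity is

    λ(t) = clip( b + A·cos(k·(φ(t) − Φ_max − s·δ)) ),

with background b (impulses·s⁻¹), modulation amplitude A, harmonic k (1
azimuthal, 2 axial), rotation-direction sign s (+1 cw, −1 ccw) and
anticipatory lead δ ≥ 0 applied against the rotation direction — a constant
angular lead being the simplest mechanism producing the observed cw/ccw
mismatch, which it makes exactly 2δ in expectation. Opponent neurons clip
at zero and may fall below background (full inhibition at the
anti-preferred angle when A ≥ b); non-opponent neurons add only the
positive half-wave, b + max(0, A·cos·). Off periods sit at b. Optional
exponential onset transients (amplitude, time constant τ) follow each
lights-on event, and an offset response (phasic or inhibitory) each
lights-off. Cosine tuning is the minimal model reproducing the
unimodal/bimodal circular histograms of these neurons; it is first-order —
real cells show additional asymmetries, velocity dependence and
non-stationarity that this generator deliberately omits, so passing
recovery tests demonstrates correctness of the analysis, not realism of
every biological detail.

Sampling uses thinning: homogeneous candidates at the ceiling
λ_max = b + A + |onset amplitude| are accepted with probability
λ(t)/λ_max. A single integer seed (NumPy PCG64) governs each simulation.

### Presets

`scenario_library()` provides six presets whose preferred angles and
background rates follow published per-neuron values: `PC4` (axial
opponent, Φ_max 51.8°, b = 9.0), `PC5_UV` (azimuthal opponent, 94.3°,
b = 30.7, complete inhibition opposite the preferred azimuth),
`PC5_GREEN` (azimuthal non-opponent, 84.4°), `LOXPN1` (axial, 128.2°,
δ = 23.3° so the cw/ccw mismatch is ≈ 46.6°, with a phasic lights-on
burst), `TB1c` (untuned control, A = 0, b = 17.3) and `TB4_LOW`
(low-background weak excitation, b = 4.9). For `PC4` the amplitude is
A = 2b: for the floored opponent cosine, the pooled-spike vector length on
doubled angles at A/b = 2 is r ≈ 0.66, matching the observed r = 0.67 of
that cell.

## Numerical and validation choices

* Statistics are computed in radians via complex exponentials; a resultant
  below 10⁻¹² is treated as vanished (mean direction undefined).
* Default problem sizes: validation studies use the standard session
  (3 cw + 3 ccw rotations, off gaps for ≥ 2 background bins), 200 seeded
  sessions for parameter recovery, 2,000 for null calibration, 100 per δ
  for the anticipation law, and 20 amplitude levels × 50 seeds for the
  r-monotonicity check.
* The type-I error of the χ²₂ linear-circular test is slightly inflated
  (~0.07) when per-bin counts are low (short two-turn sessions); under the
  standard session (≈ 40+ spikes per bin for typical backgrounds) the
  empirical rate is within the binomial envelope of the nominal 0.05.
* The thinning validity check compares binned spike counts with the
  trapezoid-integrated intensity via Pearson's χ². Its p-values are
  uniform under the model, but the χ² approximation has a slightly heavy
  tail when expected counts are ~10–30, so the check uses 3-s bins
  (expected ≈ 60 counts per bin), a standard validity requirement for the
  Pearson statistic.
* Serialized artifacts use degrees and impulses·s⁻¹ exclusively; CSV is
  UTF-8 with dot decimals and mandatory headers; every output directory
  carries a JSON manifest with the configuration, seed and package
  version needed to regenerate it.

## Known limitations

* No spike sorting, burst detection, raw-voltage event extraction or
  vendor-format readers: input is a spike time-stamp CSV.
* The generator does not model membrane dynamics, rotation-velocity-gated
  responses, or cells whose cw and ccw tunings are orthogonal; the
  anticipatory lead is constant rather than velocity dependent.
* The analytic confidence arc is a large-sample approximation; at very
  small n or low r it is undefined and reported as such.
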