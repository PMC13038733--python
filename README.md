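# skytuner

Angular-tuning analysis of spike trains from sky-compass neurons, with a
matched synthetic-electrophysiology generator.

## The problem

Many insects steer by celestial cues: the polarization pattern of the blue
sky and the azimuth of the sun. Neurons of this sky-compass pathway are
characterised by rotating a visual stimulus around the animal — a linear
polarizer overhead (whose E-vector orientation is an *axial* quantity,
defined only modulo 180°), or an unpolarized light spot circling the head
(an azimuth, periodic with 360°) — while recording spikes intracellularly.
The analysis question is always the same: does the firing rate depend on
the presented angle, and if so, at which angle Φ_max is the neuron maximally
excited, and how strongly?

`skytuner` implements that analysis as a tested, reusable pipeline for
anyone working with rotating-stimulus electrophysiology:

* map each spike time to the stimulus angle presented at that instant,
  separately for every full 360° rotation ("trial"), with the
  onset-transient first rotation of each stimulus excluded;
* estimate background activity (mean ± SD) from 1-s bins of stimulus-off
  periods;
* bin spikes into 10/15/20° angular bins, convert to firing rates via the
  per-bin dwell time (bin width ÷ angular velocity), and average across
  cw/ccw trial pairs;
* summarise tuning with circular statistics — preferred angle Φ_max,
  mean-vector length *r* ∈ [0, 1], circular SD, and a 95% confidence arc —
  using the angle-doubling device for axial (polarizer) data;
* gate significance with the linear-circular correlation between per-bin
  firing rate *x* and bin angle φ:

      R² = (r²_xc + r²_xs − 2 r_xc r_xs r_cs) / (1 − r²_cs),

  where r_xc = corr(x, cos φ), r_xs = corr(x, sin φ),
  r_cs = corr(cos φ, sin φ); under the null n·R² ~ χ² with 2 df. R² is
  reported only when p < 0.05;
* classify spatial/polarization opponency (excitation above background at
  Φ_max with inhibition below background at the anti-preferred angle
  Φ_min) and quantify the cw/ccw Φ_max mismatch produced by anticipatory
  tuning shifts.

Because real recordings of this kind are rarely deposited, the package
ships a generator (`skytuner.simulate`) that draws spike trains from an
inhomogeneous Poisson process with cosine rate modulation locked to the
rotating stimulus — including opponent inhibition, onset transients, and a
fixed anticipatory lead δ against rotation direction — so every stage of
the pipeline can be validated against known ground truth.

## Worked example

Simulate the `PC4` preset — an opponent, axially tuned commissural neuron
with true Φ_max = 51.8°, background 9.0 impulses s⁻¹ — under a standard
session (3 clockwise + 3 counterclockwise polarizer rotations at 40° s⁻¹),
then analyze it:

```sh
skytuner simulate --preset PC4 --seed 1 --out demo/ --velocity 40
skytuner analyze demo/spikes.csv demo/protocol.yaml --out demo/results
```

which prints

```
PC4: 1113 spikes over 114 s -> demo
polarizer_blue_both: n=5 phi_max=52.5 deg r=0.65 R2=0.92 (p=1.52e-05)
polarizer_blue_ccw: n=3 phi_max=54.4 deg r=0.67 R2=0.86 (p=3.3e-05)
polarizer_blue_cw: n=2 phi_max=49.7 deg r=0.64 R2=0.90 (p=2.02e-05)
```

Read: pooling the 5 retained rotations (the first of 6 is excluded as the
onset transient), the estimated preferred polarization angle is 52.5° —
within a degree of the generative truth 51.8° — with vector strength
r = 0.65 and a highly significant rate–angle correlation (R² = 0.92). The
`demo/results/` bundle contains per-group JSON results, binned tuning-curve
and polar-plot CSVs, a summary table, and a run manifest. The same API is
available in Python (`simulate_spike_train`, `compute_tuning`,
`run_analysis`, ...); example session protocols are in `examples/`.

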