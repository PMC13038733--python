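segments:
- stimulus_kind: polarizer_blue
  direction: cw
  angular_velocity: 30.0
  start_time: 30.0
  start_angle: 0.0
  n_turns: 3
  elevation: 90.0
  visual_angle: null
- stimulus_kind: polarizer_blue
  direction: ccw
  angular_velocity: 30.0
  start_time: 66.0
  start_angle: 0.0
  n_turns: 3
  elevation: 90.0
  visual_angle: null
off_intervals:
- - 0.0
  - 30.0
- - 102.0
  - 132.0
stationary_intervals: []
exclude_first_rotation: true
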