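# Four-group demo: 10-minute recordings at half-scale frame resolution.
# Groups mirror an ammonia-exposure design: a control and three exposure
# levels mapped to increasing stress values.
simulation:
  duration_s: 600
  fps: 1
  frame_width: 960
  frame_height: 540
  roi_front: [210, 70, 750, 470]   # 540 x 400 px -> 1 mm/px
  roi_top: [210, 85, 750, 455]     # 540 x 370 px -> 1 mm/px
groups:
  - label: control
    stress: 0.0
    seed: 11
  - label: low
    stress: 0.15
    seed: 12
  - label: mid
    stress: 0.3
    seed: 13
  - label: high
    stress: 1.0
    seed: 14
detection:
  threshold: 60
  min_area_px: 30
  connectivity: 8
fusion:
  x_tolerance_mm: 30.0
analysis:
  window_s: 10
  alpha: 0.05
  grid: [10, 10, 10]
validation:
  tolerance_px: 5.0
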