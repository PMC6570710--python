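# Example scene/camera configuration for `colodepth generate --config`.
# Units: cm and radians. Omitted fields fall back to package defaults.
scene:
  centerline:
    - [0.0, 0.0, 0.0]
    - [0.5, 0.2, 8.0]
    - [-0.4, 0.5, 16.0]
    - [0.3, -0.3, 24.0]
    - [0.0, 0.0, 32.0]
  base_radius: 1.5
  fold_amplitude: 0.25
  fold_frequency: 0.35        # fold cycles per cm along the axis
  polyps:                      # [axial pos cm, angle rad, footprint cm, height cm]
    - [10.0, 0.8, 0.8, 0.45]
    - [20.0, -1.9, 0.6, 0.35]
  seed: 0
camera:
  fx: 230.4
  fy: 230.4
  cx: 127.5
  cy: 127.5
  width: 256
  height: 256
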