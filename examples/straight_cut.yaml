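# Straight constant-depth cut across the top face of a synthetic box model.
# Units: mm, g, s.  Run:
#   meshlesscut simulate --config examples/straight_cut.yaml --out out/
model:
  kind: box
  extent: [40.0, 40.0, 20.0]
  spacing: 4.0
  refine_surface: true

# scalpel sweep: tip slides +x along the top face, blade plane y = 17
trajectory:
  - {tip: [8.0, 17.0, 20.0], handle: [20.0, 17.0, 30.0], depth: 6.0}
  - {tip: [10.0, 17.0, 20.0], handle: [22.0, 17.0, 30.0], depth: 6.0}
  - {tip: [12.0, 17.0, 20.0], handle: [24.0, 17.0, 30.0], depth: 6.0}
  - {tip: [14.0, 17.0, 20.0], handle: [26.0, 17.0, 30.0], depth: 6.0}
  - {tip: [16.0, 17.0, 20.0], handle: [28.0, 17.0, 30.0], depth: 6.0}
  - {tip: [18.0, 17.0, 20.0], handle: [30.0, 17.0, 30.0], depth: 6.0}

material:
  E: 3000.0            # Pa, soft-tissue scale stiffness
  support_radius: 8.8  # mm, 2.2 x lattice spacing
  dt: 0.02             # s, quasi-static batch step
  damping: 0.35        # near-critical per-step damping for relaxation

oscillation: {a: 1.0, b: 6.283185307179586, k: 1.0}

samples_per_curve: 16
per_edge: 1
opening_scale: 1.0
opening_ramp_time: 0.1
steps_per_pose: 20
seed: 1
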