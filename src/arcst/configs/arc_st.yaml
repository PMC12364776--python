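# Uncollimated static arc with shoot-through layers (Arc+ST), study defaults.
phantom: {spacing: 0.25, target: CTV_small}
plan:
  n_directions: 20
  shoot_through: true
  collimated: false
  margin_factor: 1.0
  layers_initial: 480
  layers_final: 240
  prescription: 60.0
  fractions: 30
optimizer: {maxiter: 200, tol: 1.0e-06, seed: 17}
scenario: {kind: spr_scale, spr_scale: 1.05}
output_dir: arcst_out/arc_st
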