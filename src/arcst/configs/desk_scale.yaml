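# Desk-scale Arc+ST example: 5 mm grid, small target, fast end-to-end run.
phantom: {spacing: 0.5, target: CTV_small}
plan:
  n_directions: 20
  shoot_through: true
  collimated: false
  margin_factor: 1.0
  layers_initial: 480
  layers_final: 240
optimizer: {maxiter: 150, tol: 1.0e-06, seed: 17}
scenario: {kind: spr_scale, spr_scale: 1.05}
output_dir: arcst_out/desk
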