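# Collimated 3-beam IMPT with shoot-through layers.
phantom: {spacing: 0.25, target: CTV_small}
plan:
  angles: [0.0, 120.0, 240.0]
  shoot_through: true
  collimated: true
  margin_factor: 1.25
  layers_initial: 72
  layers_final: 48
optimizer: {maxiter: 200, tol: 1.0e-06, seed: 17}
output_dir: arcst_out/beams3_st
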