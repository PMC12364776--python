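# Collimated static arc (Arc+Coll), margin factor 1.25 (best performer).
phantom: {spacing: 0.25, target: CTV_small}
plan:
  n_directions: 20
  shoot_through: false
  collimated: true
  margin_factor: 1.25
  layers_initial: 480
  layers_final: 240
optimizer: {maxiter: 200, tol: 1.0e-06, seed: 17}
output_dir: arcst_out/arc_coll
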