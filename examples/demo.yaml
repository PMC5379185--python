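# Demo pipeline configuration: a two-state 13-residue loop with a
# nucleotide reporter site, toy double-well metadynamics, clustering,
# hydration and the see-saw energetics.  Runs in well under a minute.
seed: 1
output_dir: switchscape_out

loop:
  n_res: 13
  start_resid: 28
  n_frames: 300
  kappa: 50.0
  separation_deg: 90.0
  weights: [0.6, 0.4]
  reporter: [[3.0, 0.3], [6.5, 0.5]]

references:
  selection: "name CA"

projection:
  form: half_cosine
  width_deg: 2.3

metad:
  barrier: 4.0
  delta_g: 2.0
  W: 0.1
  width: 0.1
  stride_ps: 1.0
  bias_factor: 10.0
  dt: 0.002
  n_steps: 150000
  grid: [-2.0, 2.0, 161]

cluster:
  k: 4

hydration:
  density: 0.0334   # bulk-water number density, A^-3
  cutoff: 4.0
  block_len: 10

energy:
  cutoff: 10.0
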